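"""3-D cycle-consistent adversarial translation between PET-like and SPECT-like volumes.

Two generators (G_PS: PET→SPECT, G_SP: SPECT→PET) and two patch-based
discriminators (D_P, D_S) are trained on *unpaired* sets with three loss
terms: binary cross-entropy adversarial losses, an L1 cycle-consistency loss
(translate and translate back must reproduce the input) weighted 10, and an
L1 identity loss (a generator fed an image already in its output domain
should leave it unchanged) weighted 1. Optimization is Adam at a constant
learning rate (default 2e-4) with batch size 1; per step the discriminators
are updated first, then both generators jointly.

Generators are residual-block encoder–decoders (one 2x down/up level) and
discriminators emit a grid of per-patch realness probabilities; depth/width
live in ``arch_config`` so a slim desk-scale variant (for 32^3 phantoms) and
a larger variant share all code. Exact layer counts are an implementation
choice of this package. Inputs are expected max-normalized to [0, 1];
translated outputs are clamped to >= 0.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import nn
from .volume_io import Volume, require_same_grid

logger = logging.getLogger(__name__)

PET_TO_SPECT = "PET_to_SPECT"
SPECT_TO_PET = "SPECT_to_PET"


class NanLossError(RuntimeError):
    """Raised when a training step produces a non-finite loss."""


@dataclass
class LossConfig:
    """Loss weights and functional forms (BCE adversarial, L1 reconstruction)."""

    w_cycle: float = 10.0
    w_identity: float = 1.0
    w_adv: float = 1.0
    adv_form: str = "bce"
    recon_form: str = "l1"

    def __post_init__(self) -> None:
        if min(self.w_cycle, self.w_identity, self.w_adv) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class TrainConfig:
    """Optimization schedule. Defaults follow the full-scale protocol."""

    epochs: int = 200
    batch_size: int = 1
    learning_rate: float = 2e-4
    beta1: float = 0.5
    seed: int = 0
    base_channels: int = 6
    checkpoint_every: int = 0
    workdir: str | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def slim_train_config(seed: int = 0, epochs: int = 5) -> TrainConfig:
    """Desk-scale preset for 32^3 phantom experiments.

    The slim network has few parameters and sees only a handful of volumes,
    so it uses a higher constant learning rate (2e-3) than the full-scale
    default; everything else (losses, weights, update order) is identical.
    """
    return TrainConfig(epochs=epochs, learning_rate=2e-3, seed=seed, base_channels=6)


def build_generator(base: int, rng: np.random.Generator) -> nn.Sequential:
    # channel reduction happens before upsampling so the only full-resolution
    # 3^3 convolutions have few input channels (CPU cost is dominated by them)
    c = base
    return nn.Sequential(
        nn.Conv3d(1, c, rng=rng), nn.InstanceNorm(c), nn.LeakyReLU(0.2),
        nn.AvgPool2(), nn.Conv3d(c, 2 * c, rng=rng), nn.InstanceNorm(2 * c), nn.LeakyReLU(0.2),
        nn.Residual(nn.Sequential(
            nn.Conv3d(2 * c, 2 * c, rng=rng), nn.InstanceNorm(2 * c), nn.LeakyReLU(0.2),
            nn.Conv3d(2 * c, 2 * c, rng=rng), nn.InstanceNorm(2 * c),
        )),
        nn.Conv3d(2 * c, c, rng=rng), nn.InstanceNorm(c), nn.LeakyReLU(0.2),
        nn.Upsample2(),
        # linear output: a rectifying activation here cripples the L1
        # gradient wherever the pre-activation goes negative and can trap a
        # run in a zeroed-background basin; clamping to >= 0 happens at
        # inference instead
        nn.Conv3d(c, 1, rng=rng, weight_scale=0.05, bias_init=0.05),
    )


def build_discriminator(base: int, rng: np.random.Generator) -> nn.Sequential:
    c = base
    return nn.Sequential(
        nn.Conv3d(1, c, rng=rng), nn.LeakyReLU(0.2), nn.AvgPool2(),
        nn.Conv3d(c, 2 * c, rng=rng), nn.InstanceNorm(2 * c), nn.LeakyReLU(0.2), nn.AvgPool2(),
        nn.Conv3d(2 * c, 1, rng=rng), nn.Sigmoid(),
    )


@dataclass
class TranslationModel:
    """The four trained networks plus the grid/architecture contract."""

    G_PS: nn.Sequential
    G_SP: nn.Sequential
    D_P: nn.Sequential
    D_S: nn.Sequential
    arch_config: dict = field(default_factory=dict)
    grid_shape: tuple[int, int, int] | None = None

    def save(self, path: os.PathLike | str) -> None:
        arrays: dict[str, np.ndarray] = {}
        for name in ("G_PS", "G_SP", "D_P", "D_S"):
            for i, a in enumerate(getattr(self, name).state()):
                arrays[f"{name}_{i}"] = a
        meta = {"arch_config": self.arch_config, "grid_shape": list(self.grid_shape or [])}
        np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: os.PathLike | str) -> "TranslationModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            model = build_model(meta["arch_config"].get("base_channels", 6),
                                seed=0)
            model.arch_config = meta["arch_config"]
            model.grid_shape = tuple(meta["grid_shape"]) or None
            for name in ("G_PS", "G_SP", "D_P", "D_S"):
                keys = sorted((k for k in z.files if k.startswith(name + "_")),
                              key=lambda k: int(k.rsplit("_", 1)[1]))
                getattr(model, name).load_state([z[k] for k in keys])
        return model


def build_model(base_channels: int, seed: int) -> TranslationModel:
    rng = np.random.default_rng(seed)
    return TranslationModel(
        G_PS=build_generator(base_channels, rng),
        G_SP=build_generator(base_channels, rng),
        D_P=build_discriminator(base_channels, rng),
        D_S=build_discriminator(base_channels, rng),
        arch_config={"base_channels": base_channels},
    )


# ---------------------------------------------------------------------------
# Loss operations (public, oracle-checked)
# ---------------------------------------------------------------------------

def adversarial_loss(d_scores: np.ndarray, target: str) -> float:
    """Mean BCE of per-patch probabilities against the 'real'/'fake' label."""
    if target not in ("real", "fake"):
        raise ValueError("target must be 'real' or 'fake'")
    return nn.bce(np.asarray(d_scores), 1.0 if target == "real" else 0.0)


def _as_array(x: Volume | np.ndarray) -> np.ndarray:
    return x.data if isinstance(x, Volume) else np.asarray(x)


def cycle_loss(x: Volume | np.ndarray, x_reconstructed: Volume | np.ndarray) -> float:
    """Mean absolute voxel difference between an input and its round trip."""
    if isinstance(x, Volume) and isinstance(x_reconstructed, Volume):
        require_same_grid(x, x_reconstructed)
    return nn.l1(_as_array(x), _as_array(x_reconstructed))


def identity_loss(x: Volume | np.ndarray, g_of_x: Volume | np.ndarray) -> float:
    """L1 penalty for altering an input already in the generator's output domain."""
    return cycle_loss(x, g_of_x)


def total_generator_loss(components: dict[str, float] | list[dict[str, float]],
                         cfg: LossConfig) -> float:
    """w_adv*L_adv + w_cycle*L_cyc + w_identity*L_id, summed over directions.

    ``components`` is one dict with keys ``adv``/``cycle``/``identity`` (one
    direction) or a list of such dicts (summed).
    """
    if isinstance(components, dict):
        components = [components]
    total = 0.0
    for comp in components:
        vals = (comp["adv"], comp["cycle"], comp["identity"])
        if not all(np.isfinite(v) for v in vals):
            raise NanLossError(f"non-finite loss components {comp}")
        total += cfg.w_adv * vals[0] + cfg.w_cycle * vals[1] + cfg.w_identity * vals[2]
    return float(total)


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def train(pet_set: list[Volume], spect_set: list[Volume],
          tc: TrainConfig, lc: LossConfig | None = None
          ) -> tuple[TranslationModel, pd.DataFrame]:
    """Train the four networks on unpaired sets; returns model + loss trace.

    The trace has one row per epoch with the mean adversarial losses seen by
    each discriminator's generator, the cycle and identity losses, and their
    weighted total. A non-finite loss aborts the run with the last
    checkpoint retained (if checkpointing is enabled).
    """
    if not pet_set or not spect_set:
        raise ValueError("both training sets must be nonempty")
    lc = lc or LossConfig()
    pets = [np.asarray(v.data, dtype=nn.DEFAULT_DTYPE)[None] for v in pet_set]
    spects = [np.asarray(v.data, dtype=nn.DEFAULT_DTYPE)[None] for v in spect_set]
    ref = pet_set[0]
    for v in list(pet_set) + list(spect_set):
        require_same_grid(ref, v)

    rng = np.random.default_rng(tc.seed)
    model = build_model(tc.base_channels, seed=int(rng.integers(2**31 - 1)))
    model.grid_shape = ref.shape
    opt_g = nn.Adam(model.G_PS.params() + model.G_SP.params(),
                    lr=tc.learning_rate, beta1=tc.beta1)
    opt_d = nn.Adam(model.D_P.params() + model.D_S.params(),
                    lr=tc.learning_rate, beta1=tc.beta1)

    steps = max(len(pets), len(spects))
    rows = []
    for epoch in range(1, tc.epochs + 1):
        order_p = rng.permutation(len(pets))
        order_s = rng.permutation(len(spects))
        acc = {"L_adv_P": 0.0, "L_adv_S": 0.0, "L_cyc": 0.0, "L_id": 0.0,
               "L_total": 0.0, "L_D": 0.0}
        for step in range(steps):
            p = pets[order_p[step % len(pets)]]
            s = spects[order_s[step % len(spects)]]

            # --- discriminator update (generators frozen) ---
            fake_s, _ = model.G_PS.forward(p)
            fake_p, _ = model.G_SP.forward(s)
            opt_d.zero_grad()
            l_d = 0.0
            for disc, real, fake in ((model.D_S, s, fake_s), (model.D_P, p, fake_p)):
                pr, cr = disc.forward(real)
                pf, cf = disc.forward(fake)
                l_d += 0.5 * (nn.bce(pr, 1.0) + nn.bce(pf, 0.0))
                disc.backward(0.5 * nn.bce_grad(pr, 1.0), cr)
                disc.backward(0.5 * nn.bce_grad(pf, 0.0), cf)
            opt_d.step()

            # --- generator update (both directions jointly) ---
            opt_g.zero_grad()
            model.D_P.zero_grad()
            model.D_S.zero_grad()
            fake_s, c_ps = model.G_PS.forward(p)
            rec_p, c_sp_rec = model.G_SP.forward(fake_s)
            fake_p, c_sp = model.G_SP.forward(s)
            rec_s, c_ps_rec = model.G_PS.forward(fake_p)
            id_s, c_id_s = model.G_PS.forward(s)
            id_p, c_id_p = model.G_SP.forward(p)
            ps_scores, c_ds = model.D_S.forward(fake_s)
            pp_scores, c_dp = model.D_P.forward(fake_p)

            l_adv_s = nn.bce(ps_scores, 1.0)
            l_adv_p = nn.bce(pp_scores, 1.0)
            l_cyc = nn.l1(rec_p, p) + nn.l1(rec_s, s)
            l_id = nn.l1(id_s, s) + nn.l1(id_p, p)
            l_total = lc.w_adv * (l_adv_s + l_adv_p) + lc.w_cycle * l_cyc + lc.w_identity * l_id
            if not np.isfinite(l_total):
                raise NanLossError(
                    f"non-finite loss at epoch {epoch} step {step}: "
                    f"adv=({l_adv_p}, {l_adv_s}) cyc={l_cyc} id={l_id}"
                )

            # backprop: adversarial + cycle gradients into the fakes, then
            # through their generators; identity terms go in directly.
            d_fake_s = model.D_S.backward(lc.w_adv * nn.bce_grad(ps_scores, 1.0), c_ds)
            d_fake_s = d_fake_s + model.G_SP.backward(
                lc.w_cycle * nn.l1_grad(rec_p, p), c_sp_rec)
            model.G_PS.backward(d_fake_s, c_ps)
            d_fake_p = model.D_P.backward(lc.w_adv * nn.bce_grad(pp_scores, 1.0), c_dp)
            d_fake_p = d_fake_p + model.G_PS.backward(
                lc.w_cycle * nn.l1_grad(rec_s, s), c_ps_rec)
            model.G_SP.backward(d_fake_p, c_sp)
            model.G_PS.backward(lc.w_identity * nn.l1_grad(id_s, s), c_id_s)
            model.G_SP.backward(lc.w_identity * nn.l1_grad(id_p, p), c_id_p)
            opt_g.step()
            model.D_P.zero_grad()
            model.D_S.zero_grad()

            acc["L_adv_P"] += l_adv_p
            acc["L_adv_S"] += l_adv_s
            acc["L_cyc"] += l_cyc
            acc["L_id"] += l_id
            acc["L_total"] += l_total
            acc["L_D"] += l_d
        row = {"epoch": epoch, **{k: v / steps for k, v in acc.items()}}
        rows.append(row)
        logger.info("epoch %d: %s", epoch, {k: round(v, 4) for k, v in row.items() if k != "epoch"})
        if tc.checkpoint_every and tc.workdir and epoch % tc.checkpoint_every == 0:
            os.makedirs(tc.workdir, exist_ok=True)
            model.save(os.path.join(tc.workdir, f"checkpoint_epoch{epoch:04d}.npz"))
    trace = pd.DataFrame(rows)
    if tc.workdir:
        os.makedirs(tc.workdir, exist_ok=True)
        trace.to_csv(os.path.join(tc.workdir, "loss_trace.csv"), index=False)
    return model, trace


def translate(model: TranslationModel, vol: Volume, direction: str) -> Volume:
    """Apply a trained generator; output on the same grid, clamped >= 0."""
    if model.grid_shape is not None and vol.shape != tuple(model.grid_shape):
        raise ValueError(f"volume shape {vol.shape} does not match model grid "
                         f"{tuple(model.grid_shape)}")
    if direction == PET_TO_SPECT:
        gen = model.G_PS
    elif direction == SPECT_TO_PET:
        gen = model.G_SP
    else:
        raise ValueError(f"direction must be {PET_TO_SPECT} or {SPECT_TO_PET}")
    y, _ = gen.forward(np.asarray(vol.data, dtype=nn.DEFAULT_DTYPE)[None])
    return vol.with_data(np.clip(y[0], 0.0, None))


def loss_config_dict(lc: LossConfig) -> dict:
    return asdict(lc)
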