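"""End-to-end workflow: simulate → preprocess → train → translate → quantify
→ FID → classify, driven by one config mapping with a single master seed.

Every stage seed is derived deterministically from the master seed, so a
re-run with the same config reproduces all deterministic outputs. The run
directory receives per-stage outputs as they complete plus a JSON manifest
(config hash, package version, stage seeds, timestamps); a stage failure
stops the run with prior outputs intact.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import __version__, classify, cyclegan, perceptual, phantom, preprocess, quantify
from .volume_io import Volume, write_volume

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "preprocess", "train", "translate", "quantify", "fid", "classify")

#: Full default configuration. Values under ``preprocess``/``train``/
#: ``classify`` are the standard full-scale protocol (smoothing FWHM per
#: modality, loss weights, optimizer schedule); sizes default to a
#: desk-scale demo so the pipeline runs end-to-end on one CPU.
DEFAULT_CONFIG: dict = {
    "seed": None,          # required: master seed (int)
    "outdir": None,        # required: run directory
    "log_level": "INFO",
    "phantom": {
        "grid_shape": [32, 32, 32],
        "spacing_mm": [2.0, 2.0, 2.0],
        "n_train_nc": 3, "n_train_pd": 3,
        "n_test_nc": 10, "n_test_pd": 10,
    },
    "preprocess": {
        "pet_fwhm_mm": 10.0,       # protocol smoothing for PET
        "spect_fwhm_mm": 6.0,      # protocol smoothing for SPECT
        "post_fwhm": 1.7,          # post-generation de-texturing filter
        "post_fwhm_units": "mm",
    },
    "train": {
        "epochs": 5, "batch_size": 1, "learning_rate": 2e-3,
        "base_channels": 6, "w_cycle": 10.0, "w_identity": 1.0, "w_adv": 1.0,
        "checkpoint_every": 0,
    },
    "classify": {
        "epochs": 25, "early_stop_patience": 20,
        "initial_lr": 3e-3, "lr_factor": 0.5, "lr_patience": 8,
        "base_channels": 6, "batch_size": 6,
    },
    "fid": {"n_boot": 200, "embed_dim": 8, "embed_seed": 17},
}

REQUIRED_KEYS = ("seed", "outdir")


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge user config over defaults; unknown or missing keys are named errors."""
    merged = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict, path: str = "") -> None:
        for key, val in src.items():
            full = f"{path}{key}"
            if key not in dst:
                raise ConfigError(f"unknown config key: {full!r}")
            if isinstance(dst[key], dict) and isinstance(val, dict):
                merge(dst[key], val, full + ".")
            else:
                dst[key] = val

    merge(merged, config or {})
    for key in REQUIRED_KEYS:
        if merged[key] is None:
            raise ConfigError(f"missing required config key: {key!r}")
    merged["seed"] = int(merged["seed"])
    return merged


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    idx = STAGE_ORDER.index(stage)
    return int(np.random.SeedSequence([int(master), idx]).generate_state(1)[0] % (2**31 - 1))


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Execute all stages; returns a results dict and writes the run manifest."""
    cfg = validate_config(config)
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    master = cfg["seed"]
    manifest: dict = {
        "config": cfg, "config_hash": _config_hash(cfg), "package_version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"), "stages": {},
    }
    results: dict = {}

    pc = cfg["phantom"]
    shape, spacing = tuple(pc["grid_shape"]), tuple(pc["spacing_mm"])

    # --- simulate ---
    t0 = time.time()
    seeds = {s: stage_seed(master, s) for s in STAGE_ORDER}
    train_pet = phantom.generate_cohort(pc["n_train_nc"], pc["n_train_pd"], "PET_like",
                                        seeds["simulate"], shape, spacing)
    train_spect = phantom.generate_cohort(pc["n_train_nc"], pc["n_train_pd"], "SPECT_like",
                                          seeds["simulate"] + 1, shape, spacing)
    test_pet = phantom.generate_cohort(pc["n_test_nc"], pc["n_test_pd"], "PET_like",
                                       seeds["simulate"] + 2, shape, spacing)
    test_spect = phantom.generate_cohort(pc["n_test_nc"], pc["n_test_pd"], "SPECT_like",
                                         seeds["simulate"] + 3, shape, spacing)
    phantom.write_cohort(train_pet, os.path.join(outdir, "phantoms", "train_pet"))
    phantom.write_cohort(train_spect, os.path.join(outdir, "phantoms", "train_spect"))
    phantom.write_cohort(test_pet, os.path.join(outdir, "phantoms", "test_pet"))
    phantom.write_cohort(test_spect, os.path.join(outdir, "phantoms", "test_spect"))
    manifest["stages"]["simulate"] = {"seed": seeds["simulate"], "seconds": time.time() - t0}

    # --- preprocess: smooth -> normalize (training max, frozen) -> mask ---
    t0 = time.time()
    ppc = cfg["preprocess"]
    brain = phantom.brain_mask(shape, spacing)
    fwhm = {"PET_like": ppc["pet_fwhm_mm"], "SPECT_like": ppc["spect_fwhm_mm"]}

    def smooth_set(subjects, modality):
        return [preprocess.gaussian_smooth(s.volume, fwhm[modality]) for s in subjects]

    sm_train_pet = smooth_set(train_pet, "PET_like")
    sm_train_spect = smooth_set(train_spect, "SPECT_like")
    norms = {
        "PET_like": preprocess.fit_normalization(sm_train_pet, "train_pet"),
        "SPECT_like": preprocess.fit_normalization(sm_train_spect, "train_spect"),
    }

    def finish(vols, modality):
        return [preprocess.apply_brain_mask(
            preprocess.apply_normalization(v, norms[modality]), brain) for v in vols]

    pp_train_pet = finish(sm_train_pet, "PET_like")
    pp_train_spect = finish(sm_train_spect, "SPECT_like")
    pp_test_pet = finish(smooth_set(test_pet, "PET_like"), "PET_like")
    pp_test_spect = finish(smooth_set(test_spect, "SPECT_like"), "SPECT_like")
    manifest["stages"]["preprocess"] = {
        "seconds": time.time() - t0, "order": "smooth->normalize->mask",
        "normalization_constants": {k: v.dataset_max for k, v in norms.items()},
    }

    # --- train ---
    t0 = time.time()
    tcfg = cfg["train"]
    tc = cyclegan.TrainConfig(
        epochs=tcfg["epochs"], batch_size=tcfg["batch_size"],
        learning_rate=tcfg["learning_rate"], seed=seeds["train"],
        base_channels=tcfg["base_channels"], checkpoint_every=tcfg["checkpoint_every"],
        workdir=os.path.join(outdir, "model"),
    )
    lc = cyclegan.LossConfig(w_cycle=tcfg["w_cycle"], w_identity=tcfg["w_identity"],
                             w_adv=tcfg["w_adv"])
    model, trace = cyclegan.train(pp_train_pet, pp_train_spect, tc, lc)
    model.save(os.path.join(outdir, "model", "model_final.npz"))
    manifest["stages"]["train"] = {"seed": seeds["train"], "seconds": time.time() - t0,
                                   "final_losses": trace.iloc[-1].to_dict()}

    # --- translate test PET -> synthetic SPECT, then mask + post-smooth ---
    t0 = time.time()
    syn_dir = os.path.join(outdir, "synthetic_spect")
    os.makedirs(syn_dir, exist_ok=True)
    synthetic: list[Volume] = []
    for subj, vol in zip(test_pet, pp_test_pet):
        out = cyclegan.translate(model, vol, cyclegan.PET_TO_SPECT)
        out = preprocess.postprocess_generated_volume(
            out, brain, ppc["post_fwhm"], ppc["post_fwhm_units"])
        synthetic.append(out)
        write_volume(out, os.path.join(syn_dir, f"syn_{subj.subject_id}.nii.gz"))
    manifest["stages"]["translate"] = {"seconds": time.time() - t0, "n": len(synthetic)}

    # --- quantify the three test sets ---
    t0 = time.time()
    def quantify_set(vols, subjects, tag):
        reps = [quantify.report(v, s.atlas, subject_id=f"{tag}_{s.subject_id}",
                                cohort=s.cohort) for v, s in zip(vols, subjects)]
        quantify.reports_frame(reps).to_csv(os.path.join(outdir, f"binding_{tag}.csv"),
                                            index=False)
        quantify.cohort_table(reps).to_csv(os.path.join(outdir, f"binding_{tag}_cohort.csv"),
                                           index=False)
        return reps

    reps = {
        "synthetic_spect": quantify_set(synthetic, test_pet, "synthetic_spect"),
        "real_spect": quantify_set(pp_test_spect, test_spect, "real_spect"),
        "real_pet": quantify_set(pp_test_pet, test_pet, "real_pet"),
    }
    results["binding"] = {k: quantify.cohort_table(v).to_dict("records")
                          for k, v in reps.items()}
    manifest["stages"]["quantify"] = {"seconds": time.time() - t0}

    # --- FID with bootstrap comparison ---
    t0 = time.time()
    fcfg = cfg["fid"]
    emb = perceptual.RandomProjectionEmbedder(d=fcfg["embed_dim"], seed=fcfg["embed_seed"])
    fid_res = perceptual.bootstrap_fid_compare(
        synthetic, pp_test_spect, pp_test_pet,
        n_boot=fcfg["n_boot"], seed=seeds["fid"], embedder=emb)
    with open(os.path.join(outdir, "fid.json"), "w") as fh:
        json.dump(fid_res.to_dict(), fh, indent=2)
    results["fid"] = fid_res.to_dict()
    manifest["stages"]["fid"] = {"seed": seeds["fid"], "seconds": time.time() - t0}

    # --- classifier: train on synthetic SPECT, test on native SPECT-like ---
    t0 = time.time()
    ccfg = cfg["classify"]
    label = {"NC": classify.NC, "PD": classify.PD}
    train_items = [(v, label[s.cohort]) for v, s in zip(synthetic, test_pet)]
    test_items = [(v, label[s.cohort]) for v, s in zip(pp_test_spect, test_spect)]
    ccfg_obj = classify.ClassifierConfig(
        epochs=ccfg["epochs"], early_stop_patience=ccfg["early_stop_patience"],
        initial_lr=ccfg["initial_lr"], lr_factor=ccfg["lr_factor"],
        lr_patience=ccfg["lr_patience"], seed=seeds["classify"],
        base_channels=ccfg["base_channels"], batch_size=ccfg["batch_size"])
    clf, clf_trace = classify.train_classifier(train_items, None, ccfg_obj)
    clf_trace.to_csv(os.path.join(outdir, "classifier_trace.csv"), index=False)
    rep = classify.evaluate(clf, test_items)
    with open(os.path.join(outdir, "classifier_metrics.json"), "w") as fh:
        json.dump(rep.as_percent(), fh, indent=2)
    pd.DataFrame({"fpr": rep.roc_fpr, "tpr": rep.roc_tpr}).to_csv(
        os.path.join(outdir, "classifier_roc.csv"), index=False)
    results["classifier"] = rep.as_percent()
    manifest["stages"]["classify"] = {"seed": seeds["classify"], "seconds": time.time() - t0}

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
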