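"""Configuration, orchestration, and file I/O for end-to-end runs.

A single YAML config (schema-validated, unknown keys rejected) drives the
pipeline: preprocess -> entropy -> microstates -> features -> association
screening -> prediction.  Every stage writes CSV/JSON artifacts into the
output directory together with the config and seed that produced them, so
a run is reproducible bit-exactly from (inputs, config, seed).  Per-subject
failures are quarantined and logged; only cohort-level errors abort a run.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import entropy as ent
from . import features as feat
from . import inference as inf
from . import microstates as ms
from . import prediction as pred
from . import preprocess as prep
from . import synthetic as syn
from .montage import channel_adjacency

logger = logging.getLogger("eegcomplexity")

#: Full default configuration; mirrors each stage's canonical parameters.
DEFAULT_CONFIG: dict = {
    "paths": {
        "data_dir": ".",
        "subject_table": "subjects.csv",
        "output_dir": "output",
    },
    "seed": 0,
    "preprocess": {
        "hp": 0.1,
        "lp": 40.0,
        "fs_out": 250.0,
        "trim": 10.0,
        "epoch": 2.0,
        "reject": 1e-4,
    },
    "entropy": {
        "m": 2,
        "r_fuzzy": 0.2,
        "r_factor": 0.2,
        "n_bins": 100,
        "n_scales": 20,
        "r_mode": "per_scale",
    },
    "microstates": {
        "k": 5,
        "n_init": 1000,
    },
    "inference": {
        "alpha": 0.05,
        "n_perm": 100,
        "confounds": ["age", "n_removed_epochs"],
    },
    "prediction": {
        "threshold": 0.05,
        "k_folds": 10,
        "n_divisions": 100,
        "n_perm": 1000,
        "signed": True,
    },
}


def _merge_validate(user: dict, defaults: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (user or {}).items():
        if key not in defaults:
            raise prep.InvalidParameterError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise prep.InvalidParameterError(f"config key {path}{key} must be a mapping")
            out[key] = _merge_validate(val, defaults[key], f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults merged with a YAML file and explicit overrides; strict keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge_validate(user, cfg)
    if overrides:
        cfg = _merge_validate(overrides, cfg)
    return cfg


def _entropy_params(cfg: dict) -> ent.EntropyParams:
    e = cfg["entropy"]
    return ent.EntropyParams(
        m=e["m"],
        r_fuzzy=e["r_fuzzy"],
        r_factor=e["r_factor"],
        n_bins=e["n_bins"],
        scales=tuple(range(1, e["n_scales"] + 1)),
        r_mode=e["r_mode"],
    )


def run_pipeline(config: dict, log_path: str | Path | None = None) -> Path:
    """Execute all stages on the cohort named by the config.

    Expects ``paths.data_dir`` to hold one BrainVision/EDF recording per
    subject (named by ``subject_id``) and ``paths.subject_table`` with at
    least ``subject_id`` and ``score`` columns.  Returns the output
    directory.
    """
    outdir = Path(config["paths"]["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    handler = None
    if log_path is not None:
        handler = logging.FileHandler(log_path)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, outdir)
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def _find_recording(data_dir: Path, subject_id: str) -> Path:
    for ext in (".vhdr", ".edf"):
        p = data_dir / f"{subject_id}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no recording for {subject_id} in {data_dir}")


def _run_pipeline(config: dict, outdir: Path) -> Path:
    (outdir / "config.yaml").write_text(yaml.safe_dump(config))
    data_dir = Path(config["paths"]["data_dir"])
    table = pd.read_csv(data_dir / config["paths"]["subject_table"])
    seed = int(config["seed"])
    params = _entropy_params(config)
    k = config["microstates"]["k"]
    n_init = config["microstates"]["n_init"]

    # stage 1: preprocess + entropy per subject (quarantine failures)
    kept_rows, epoched, profiles, qc_rows = [], [], [], []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        try:
            rec = prep.read_recording(_find_recording(data_dir, sid))
            ep, report = prep.preprocess_recording(rec, **config["preprocess"])
            if not report["keep"]:
                raise prep.UnrecoverableRecordingError(
                    f"excluded: {report['n_epochs_removed']}/{report['n_epochs_total']} epochs removed"
                )
            profile = ent.entropy_profile(ep, params)
        except Exception as exc:  # noqa: BLE001 - quarantine any subject failure
            logger.warning("subject %s quarantined: %s", sid, exc)
            qc_rows.append({"subject_id": sid, "status": f"quarantined: {exc}"})
            continue
        qc_rows.append(
            {
                "subject_id": sid,
                "status": "ok",
                "bad_channels": ",".join(report["bad_channels"]),
                "n_epochs_removed": report["n_epochs_removed"],
                "n_epochs_total": report["n_epochs_total"],
            }
        )
        kept_rows.append(row)
        epoched.append(ep)
        profiles.append(profile)
    pd.DataFrame(qc_rows).to_csv(outdir / "qc.csv", index=False)
    if len(kept_rows) < 2:
        raise prep.UnrecoverableRecordingError("fewer than 2 subjects survived QC")
    subjects = pd.DataFrame(kept_rows).reset_index(drop=True)
    subjects["n_removed_epochs"] = [ep.n_removed for ep in epoched]

    # stage 2: microstates (two-level fit on concatenated retained epochs)
    recs = [
        prep.Recording(data=ep.concatenated(), fs=ep.fs, layout=ep.layout,
                       reference="average")
        for ep in epoched
    ]
    pk_maps = [ms.peak_maps(r) for r in recs]
    individual, group = ms.fit_individual_then_group(pk_maps, k=k, n_init=n_init, seed=seed)
    measures = [ms.microstate_measures(ms.backfit(r, group)) for r in recs]
    pd.DataFrame(
        group.maps.T, index=list(recs[0].layout.labels),
        columns=[f"state_{j}" for j in range(k)],
    ).to_csv(outdir / "group_maps.csv")
    (outdir / "group_maps.json").write_text(
        json.dumps({"gev": group.gev, "k": k, "seed": seed, "level": group.level})
    )

    # stage 3: features
    full_vectors = [feat.assemble_features(p, m) for p, m in zip(profiles, measures)]
    cand_vectors = [feat.candidate_features(p, m) for p, m in zip(profiles, measures)]
    full_table = feat.build_subject_table(full_vectors, subjects)
    cand_table = feat.build_subject_table(cand_vectors, subjects)
    for sid, cols in full_table.attrs["dropped"]:
        logger.warning("subject %s dropped from analyses (missing %s...)", sid, cols)
    full_table.to_csv(outdir / "features.csv", index=False)
    cand_table.to_csv(outdir / "candidates.csv", index=False)

    # stage 4: association screening on the candidate pool
    confounds = [c for c in config["inference"]["confounds"] if c in cand_table.columns]
    constant = [c for c in confounds if cand_table[c].nunique() <= 1]
    if constant:
        logger.info("dropping constant confounds: %s", constant)
        confounds = [c for c in confounds if c not in constant]
    C = cand_table[confounds].to_numpy(float) if confounds else None
    y = cand_table["score"].to_numpy(float)
    cand_cols = list(cand_vectors[0].index)
    assoc = []
    for col in cand_cols:
        r, p = inf.partial_pearson(cand_table[col].to_numpy(float), y, C)
        assoc.append({"feature": col, "r": r, "p": p})
    assoc = pd.DataFrame(assoc)
    assoc["p_adj"] = inf.fdr_bh(assoc["p"].to_numpy())
    assoc.to_csv(outdir / "associations.csv", index=False)

    # stage 5: internal prediction
    pcfg = config["prediction"]
    n_subj = len(cand_table)
    k_folds = min(pcfg["k_folds"], max(2, n_subj // 2))
    result = pred.permutation_test_internal(
        cand_table[cand_cols].to_numpy(float), y, C,
        k=k_folds, threshold=pcfg["threshold"],
        n_divisions=pcfg["n_divisions"], n_perm=pcfg["n_perm"],
        signed=pcfg["signed"], seed=seed,
    )
    model = pred.fit_full_model(
        cand_table, cand_cols, "score", confounds or None,
        threshold=pcfg["threshold"], signed=pcfg["signed"],
    )
    model.to_json(outdir / "model.json")
    (outdir / "prediction.json").write_text(json.dumps({
        "observed_mean_cv_r": result.observed,
        "p_value": result.p_value,
        "significant": result.significant,
        "n_divisions": result.n_divisions,
        "n_permutations": result.n_permutations,
        "n_pos_features": int(model.pos_mask.sum()),
        "n_neg_features": int(model.neg_mask.sum()),
        "seed": seed,
    }, indent=1))
    logger.info("pipeline complete: %d subjects, CV r=%.3f (p=%.4f)",
                n_subj, result.observed, result.p_value)
    return outdir


def make_demo(
    outdir: str | Path,
    n_subjects: int = 30,
    duration: float = 60.0,
    seed: int = 0,
    effect_spec: dict[str, float] | None = None,
) -> tuple[Path, Path]:
    """Write a small synthetic cohort plus a matching config.

    Returns ``(data_dir, config_path)``; ``run_pipeline(load_config(config_path))``
    works on it out of the box.  The short default duration keeps the demo
    quick; production-scale simulations use the 280-s default of
    ``SimulationParams``.
    """
    outdir = Path(outdir)
    data_dir = outdir / "data"
    params = syn.SimulationParams(
        n_subjects=n_subjects, duration=duration, seed=seed,
        effect_spec=effect_spec or {},
    )
    cohort = syn.simulate_cohort(params)
    syn.write_cohort(cohort, data_dir)
    cfg = load_config(overrides={
        "paths": {
            "data_dir": str(data_dir),
            "subject_table": "subjects.csv",
            "output_dir": str(outdir / "output"),
        },
        "seed": seed,
        "microstates": {"n_init": 50},
        "prediction": {"n_divisions": 10, "n_perm": 100},
    })
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(cfg))
    return data_dir, config_path


def associate_mse_clusters(
    mse_stack: np.ndarray,
    scores: np.ndarray,
    layout,
    confounds: np.ndarray | None = None,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
) -> inf.ClusterPermutationResult:
    """Channel x scale MSE cluster-permutation screening for a cohort."""
    adjacency = channel_adjacency(layout)
    return inf.mse_cluster_permutation(
        mse_stack, scores, adjacency, confounds, n_perm=n_perm, alpha=alpha, seed=seed
    )
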