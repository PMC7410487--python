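"""Study orchestration: configuration, seeding, I/O, and the full pipeline.

``run_study`` composes the stages end to end at a configurable scale:
synthetic stimuli/features -> HRF convolution -> simulated voxel cohort ->
per-subject encoding (identification, best-feature maps) and decoding
(reconstruction grids, marginal profiles) -> selectivity statistics and
group-level permutation tests.  All randomness flows from one master seed
through named per-stage substreams, so a config plus seed reproduces every
numeric output.  Results are written as tidy TSV tables plus a JSON
manifest with seeds and file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import auditory, decoding, encoding, stats, synthetic


@dataclass
class StudyConfig:
    """Defaults mirror the original design where applicable: 8 runs of 519
    snippets (TR 947 ms), fourfold run-level CV, 25-value lambda grid,
    1000 subject-level and 10,000 group-level permutations."""

    grid_mode: str = "roi_decoding"
    n_runs: int = 8
    snippets_per_run: int = 519
    feature_source: str = "surrogate"        # 'surrogate' | 'filterbank'
    sampling_rate: float = 16000.0
    component_ripples: list = field(default_factory=lambda: [
        {"rate_hz": 4.0, "scale_cyc_per_oct": 0.8, "depth": 1.0},
        {"rate_hz": 8.0, "scale_cyc_per_oct": 2.0, "depth": 1.0},
    ])
    n_young: int = 2
    n_old: int = 2
    n_voxels: int = 200
    bandwidth_young: float = synthetic.DEFAULT_BANDWIDTH_YOUNG
    bandwidth_old: float = synthetic.DEFAULT_BANDWIDTH_OLD
    noise_sd: float = synthetic.DEFAULT_NOISE_SD
    rate_focus: bool = True
    n_folds: int = 4
    n_perm_subject: int = 1000
    n_perm_group: int = 10000
    run_subject_null: bool = False
    seed: int = 0
    out_dir: str = "results"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _stage_seeds(master_seed: int) -> dict[str, int]:
    """Named per-stage substreams derived from one master seed (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    names = ["features", "cohort", "responses", "null", "group"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _log(msg: str) -> None:
    print(f"[modenc {time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def build_features(cfg: StudyConfig, seed: int) -> auditory.FeatureMatrix:
    """Raw (pre-HRF) snippet-by-feature matrix per the configured source."""
    if cfg.feature_source == "surrogate":
        return synthetic.surrogate_feature_matrix(
            cfg.n_runs, cfg.snippets_per_run, cfg.grid_mode, seed=seed
        )
    if cfg.feature_source == "filterbank":
        stream = synthetic.make_stimulus_stream(
            n_runs=cfg.n_runs,
            run_duration_s=cfg.snippets_per_run * auditory.TR_SECONDS,
            sampling_rate=cfg.sampling_rate,
            component_ripples=cfg.component_ripples,
            seed=seed,
        )
        snippets, labels = auditory.cut_snippets(stream)
        return auditory.build_feature_matrix(snippets, labels, cfg.sampling_rate, cfg.grid_mode)
    raise ValueError(f"unknown feature_source {cfg.feature_source!r}")


def run_study(cfg: StudyConfig, seed: int | None = None, out_dir=None) -> dict:
    """Execute the full study; returns the in-memory results bundle and
    writes TSV tables plus a manifest under ``out_dir``."""
    seed = cfg.seed if seed is None else seed
    seeds = _stage_seeds(seed)
    out = Path(cfg.out_dir if out_dir is None else out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "features"
    try:
        _log("building feature matrix")
        s_raw = build_features(cfg, seeds["features"])
        s_conv = auditory.hrf_convolve(s_raw)
        s_sim = encoding.zscore_feature_matrix(s_conv)

        stage = "cohort"
        axes = s_raw.axes
        weights = synthetic.rate_focus_weights(len(axes.rates)) if cfg.rate_focus else None
        cohort = synthetic.make_cohort(
            cfg.n_young, cfg.n_old, cfg.n_voxels,
            bandwidth_young=cfg.bandwidth_young, bandwidth_old=cfg.bandwidth_old,
            noise_sd=cfg.noise_sd, grid_mode=cfg.grid_mode,
            rate_weights=weights, seed=seeds["cohort"],
        )
        responses = synthetic.simulate_cohort(s_sim, cohort, seed=seeds["responses"])

        stage = "encoding/decoding"
        ident_rows, sel_rows, map_rows, recon_rows = [], [], [], []
        null_rows = []
        sel_results = []
        null_rng = np.random.default_rng(seeds["null"])
        for subj in cohort.subjects:
            y = responses[subj.subject_id]
            enc = encoding.run_encoding_cv(s_conv, y, cfg.n_folds)
            for k, res in enumerate(enc.identification):
                ident_rows.append({
                    "subject": subj.subject_id, "group": subj.group_label,
                    "fold": k, "accuracy": res.accuracy, "n_test": res.n_test,
                })
            bmap = encoding.best_feature_map(enc.model.coef, axes)
            for v in range(cfg.n_voxels):
                map_rows.append({
                    "subject": subj.subject_id, "group": subj.group_label, "voxel": v,
                    "best_rate": bmap.rate[v], "best_scale": bmap.scale[v],
                    "best_frequency": bmap.frequency[v],
                })
            if cfg.run_subject_null:
                grid = decoding.permutation_null(
                    s_raw, y, n_folds=cfg.n_folds, n_perm=cfg.n_perm_subject,
                    seed=int(null_rng.integers(2**31)),
                )
                for j in range(axes.n_features):
                    null_rows.append({
                        "subject": subj.subject_id, "feature": j, "r": grid.r[j],
                        "r_chance": grid.r_chance[j], "p": grid.p[j], "z": grid.z[j],
                        "n_perm": cfg.n_perm_subject,
                    })
            else:
                grid = decoding.run_decoding_cv(s_conv, y, cfg.n_folds)
            profiles = decoding.marginal_accuracy_profiles(grid)
            sel = stats.selectivity_result(profiles, subj.subject_id, subj.group_label)
            sel_results.append(sel)
            for dim in ("rate", "scale", "frequency"):
                sel_rows.append({
                    "subject": subj.subject_id, "group": subj.group_label,
                    "dimension": dim, "si": sel.si[dim], "variance": sel.variance[dim],
                })
            for j in range(axes.n_features):
                recon_rows.append({
                    "subject": subj.subject_id, "group": subj.group_label,
                    "feature": j, "r": grid.r[j],
                })

        stage = "group stats"
        group_rows = []
        for dim in ("rate", "scale", "frequency"):
            for measure in ("si", "variance"):
                young = [getattr(s, measure)[dim] for s in sel_results if s.group_label == "young"]
                old = [getattr(s, measure)[dim] for s in sel_results if s.group_label == "old"]
                test = stats.group_permutation_test(
                    np.asarray(young), np.asarray(old),
                    n_perm=cfg.n_perm_group, seed=seeds["group"],
                )
                group_rows.append({
                    "dimension": dim, "measure": measure,
                    "mean_difference": test.observed, "p": test.p_value,
                    "cohens_d": test.effect_size, "n_perm": test.n_perm,
                    "seed": test.seed, "sides": test.sides,
                })

        stage = "write outputs"
        tables = {
            "identification.tsv": pd.DataFrame(ident_rows),
            "selectivity.tsv": pd.DataFrame(sel_rows),
            "best_feature_maps.tsv": pd.DataFrame(map_rows),
            "reconstruction.tsv": pd.DataFrame(recon_rows),
            "group_tests.tsv": pd.DataFrame(group_rows),
            "cohort_truth.tsv": cohort.to_frame(),
        }
        if null_rows:
            tables["subject_null.tsv"] = pd.DataFrame(null_rows)
        checksums = {}
        for name, df in tables.items():
            path = out / name
            df.to_csv(path, sep="\t", index=False, float_format="%.10g")
            checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest = {
            "config": dataclasses.asdict(cfg),
            "master_seed": seed,
            "stage_seeds": seeds,
            "n_features": axes.n_features,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
            "checksums": checksums,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return {"tables": tables, "manifest": manifest, "selectivity": sel_results}
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(
            {"status": "failed", "stage": stage, "error": str(exc)}, indent=2))
        raise RuntimeError(f"study failed at stage '{stage}': {exc}") from exc


# --------------------------------------------------------------------------
# Real-data ingestion (no preprocessing; assumed done upstream)
# --------------------------------------------------------------------------

def ingest_real_data(nifti_4d, mask, run_labels) -> encoding.VoxelResponseMatrix:
    """Masked volumes x voxels matrix from a 4-D NIfTI plus a binary mask.

    ``run_labels`` must give one run id per volume.
    """
    import nibabel as nib

    img = nib.load(str(nifti_4d)) if not hasattr(nifti_4d, "get_fdata") else nifti_4d
    msk = nib.load(str(mask)) if not hasattr(mask, "get_fdata") else mask
    data = img.get_fdata()
    m = msk.get_fdata().astype(bool)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI volume")
    if m.shape != data.shape[:3]:
        raise ValueError(f"mask shape {m.shape} does not match volume grid {data.shape[:3]}")
    if not np.allclose(img.affine, msk.affine, atol=1e-4):
        raise ValueError("mask affine does not match the 4-D volume affine")
    if not m.any():
        raise ValueError("empty mask")
    labels = np.asarray(run_labels)
    if len(labels) != data.shape[3]:
        raise ValueError(
            f"{data.shape[3]} volumes but {len(labels)} run labels"
        )
    return encoding.VoxelResponseMatrix(values=data[m].T, run_labels=labels)
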