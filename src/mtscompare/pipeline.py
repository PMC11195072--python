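"""End-to-end orchestration: QC, tensors, representations, evaluation,
nulls, comparison, selection, similarity, and tidy-CSV reporting."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .core_data import TimeSeriesDataset, apply_qc
from .evaluation import ClassifierSpec, CVScheme, run_repeated_cv
from .features import compute_feature_tensor
from .inference import (
    bh_adjust,
    corrected_resampled_ttest,
    gaussian_tail_pvalue,
    permutation_null,
    similarity_matrix,
)
from .representations import (
    build_fc,
    build_fc_combo,
    build_feature,
    build_region,
    build_uni_combo,
)
from .selection import select_best_by_training, select_best_spi_by_pca
from .spis import compute_spi_tensor

logger = logging.getLogger(__name__)


def _family_table(results, nulls=None):
    rows = []
    pvals = []
    for res in results:
        row = {
            "kind": res.kind,
            "unit": res.unit_id,
            "mean_balanced_accuracy": res.mean,
            "sd_balanced_accuracy": res.sd,
        }
        if nulls is not None:
            null = nulls[res.unit_id]
            row["null_mu"] = null.mu
            row["null_sigma"] = null.sigma
            row["p_value"] = gaussian_tail_pvalue(res.mean, null)
            pvals.append(row["p_value"])
        rows.append(row)
    df = pd.DataFrame(rows)
    if pvals:
        df["p_corrected"] = bh_adjust(np.array(pvals))
    return df


def run_full_comparison(
    dataset: TimeSeriesDataset,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    n_perm: int | None = None,
    run_nulls: bool = True,
    run_selection: bool = True,
) -> dict:
    """Evaluate all five representations on one dataset.

    Returns a dict of tidy DataFrames and result objects; writes them as
    CSV plus a machine-readable run manifest when ``out_dir`` is given.
    ``n_perm`` overrides the configured permutation count (useful for
    desk-scale runs).
    """
    dataset, qc = apply_qc(dataset, config.fd_threshold_mm)
    y = dataset.labels()
    scheme = CVScheme(k=config.cv_folds, r=config.cv_repeats, seed=config.seed)
    spec = ClassifierSpec()
    n_perm = n_perm if n_perm is not None else config.nulls_n

    logger.info("computing univariate feature tensor")
    features = compute_feature_tensor(dataset)
    logger.info("computing SPI tensor for %d SPIs", len(config.spis))
    spis = compute_spi_tensor(dataset, config.spis)

    families: dict[str, list] = {
        "region": [build_region(features, r) for r in dataset.region_labels],
        "feature": [build_feature(features, f) for f in config.features],
        "uni_combo": [build_uni_combo(features)],
        "fc": [build_fc(spis, s) for s in config.spis],
        "fc_combo": [build_fc_combo(spis, s, features) for s in config.spis],
    }

    out: dict = {"qc": qc, "features": features, "spis": spis, "cv_results": {}}
    tables = {}
    for kind, family in families.items():
        results = [run_repeated_cv(dm, y, scheme, spec) for dm in family]
        out["cv_results"][kind] = results
        nulls = None
        if run_nulls:
            nulls = {
                dm.unit_id: permutation_null(
                    dm, y, scheme, spec, n_perm=n_perm,
                    seed=config.nulls_seed,
                )
                for dm in family
            }
        tables[kind] = _family_table(results, nulls)

    # paired comparison: coupling alone vs coupling + local dynamics
    comp_rows = []
    for a, b in zip(out["cv_results"]["fc_combo"], out["cv_results"]["fc"]):
        cmp_res = corrected_resampled_ttest(a, b)
        comp_rows.append(
            {
                "spi": a.unit_id,
                "mean_fc_combo": a.mean,
                "mean_fc": b.mean,
                "t_corr": cmp_res.t_corr,
                "df": cmp_res.df,
                "p_two_tailed": cmp_res.p_two_tailed,
            }
        )
    tables["fc_combo_vs_fc"] = pd.DataFrame(comp_rows)

    if run_selection:
        # the 10-PC heuristic needs enough columns and training rows
        n_train_min = len(y) - (len(y) // scheme.k + 1)
        n_pcs = min(10, min(dm.n_columns for dm in families["fc"]), n_train_min)
        out["selection"] = {
            "region": select_best_by_training(families["region"], y, scheme, spec),
            "feature": select_best_by_training(families["feature"], y, scheme, spec),
            "fc": select_best_spi_by_pca(
                families["fc"], y, scheme, spec, n_pcs=n_pcs
            ),
        }

    # similarity of feature brain-maps across participants x regions
    feat_values = {
        f: features.values[:, :, j].reshape(-1)
        for j, f in enumerate(features.feature_names)
    }
    out["feature_similarity"] = similarity_matrix(feat_values)
    out["tables"] = tables

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
        manifest = {
            "config": asdict(config),
            "version": __version__,
            "n_participants": dataset.n_participants,
            "n_regions": dataset.n_regions,
            "excluded": asdict(qc),
            "config_hash": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True).encode()
            ).hexdigest(),
        }
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
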