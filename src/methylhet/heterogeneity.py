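"""Intra-tumour heterogeneity indices: variance selection, APITH, PCAR.

APITH (average pairwise intra-tumour heterogeneity) is the mean distance
over all pairs of multi-region tumour samples from one patient, which
makes it comparable across patients sampled at different depths.  PCAR
(predicted-to-chronological age ratio) divides DNA-methylation age by
chronological age; a patient is flagged methylation-homogeneous when the
maximum relative PCAR difference among their tumour samples is below 30%.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def select_top_variance(
    features: pd.DataFrame,
    tumour_samples: Sequence[str],
    fraction: float = 0.10,
    direction: str = "highest",
    coords: pd.DataFrame | None = None,
) -> list:
    """Select ``ceil(fraction * m)`` features by variance across tumour samples.

    Variance is computed across the tumour columns only.  Ties are broken
    by genomic coordinate (when ``coords`` provides ``chrom``/``pos`` per
    feature) and then by feature id, so the selection is deterministic.
    Rows missing in every tumour sample are excluded before ranking.
    ``direction='lowest'`` selects the least variable features instead.
    """
    if direction not in ("highest", "lowest"):
        raise ValueError("direction must be 'highest' or 'lowest'")
    if len(tumour_samples) < 2:
        raise ValueError("need >= 2 tumour samples")
    sub = features[list(tumour_samples)]
    var = sub.var(axis=1, ddof=1, skipna=True)
    var = var[sub.notna().any(axis=1)]
    if var.empty:
        return []
    n_sel = math.ceil(fraction * len(var))

    key = pd.DataFrame({"var": var})
    if coords is not None:
        key["chrom"] = coords.loc[key.index, "chrom"].astype(str)
        key["pos"] = coords.loc[key.index, "pos"]
    else:
        key["chrom"] = ""
        key["pos"] = 0
    key["fid"] = key.index.astype(str)
    ascending = direction == "lowest"
    key = key.sort_values(
        by=["var", "chrom", "pos", "fid"], ascending=[ascending, True, True, True],
        kind="mergesort",
    )
    return key.index[:n_sel].tolist()


def pairwise_distance(x: np.ndarray, y: np.ndarray, metric: str = "mean_abs_beta") -> float:
    """Distance between two beta-value profiles on shared non-missing features."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        return np.nan
    dx = x[ok] - y[ok]
    if metric == "mean_abs_beta":
        return float(np.mean(np.abs(dx)))
    if metric == "euclidean":
        return float(np.sqrt(np.sum(dx * dx)))
    raise ValueError(f"unknown metric {metric!r}")


def apith(samples: pd.DataFrame, metric: str = "mean_abs_beta") -> float:
    """Average pairwise ITH of a features x samples matrix for one patient.

    APITH = (2 / (n (n-1))) * sum over pairs of d(i, j); invariant to
    sample order.  With fewer than two samples the index is undefined
    (NaN).
    """
    cols = list(samples.columns)
    if len(cols) < 2:
        return np.nan
    arr = samples.to_numpy(dtype=float)
    dists = [
        pairwise_distance(arr[:, i], arr[:, j], metric)
        for i, j in combinations(range(len(cols)), 2)
    ]
    return float(np.mean(dists))


def apith_table(
    beta: pd.DataFrame,
    sample_patients: Mapping[str, str] | pd.Series,
    metric: str = "mean_abs_beta",
) -> pd.DataFrame:
    """APITH per patient from a features x samples beta matrix.

    ``sample_patients`` maps sample id to patient id; only samples present
    in the matrix are used.  Patients with a single sample get NaN.
    """
    sp = pd.Series(dict(sample_patients) if not isinstance(sample_patients, pd.Series) else sample_patients)
    rows = []
    for patient, ids in sp.groupby(sp).groups.items():
        cols = [s for s in ids if s in beta.columns]
        rows.append(
            {
                "patient_id": patient,
                "n_samples": len(cols),
                "metric": metric,
                "apith": apith(beta[cols], metric) if len(cols) >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("patient_id").reset_index(drop=True)


def pcar_summary(
    ages: pd.DataFrame, homogeneity_bound: float = 0.30
) -> pd.DataFrame:
    """Per-sample PCAR and per-patient methylation-age homogeneity flag.

    ``ages`` needs columns sample_id, patient_id, dnam_age, chrono_age
    (years); rows with a missing DNAm age are excluded (logged).  PCAR =
    dnam_age / chrono_age.  Per patient, the maximum relative difference
    among tumour-sample PCARs is (max - min) / min; the patient is
    homogeneous when it is strictly below ``homogeneity_bound``.  A single
    usable sample is homogeneous by convention.
    """
    df = ages.copy()
    if (df["chrono_age"] <= 0).any():
        raise ValueError("chronological age must be positive")
    missing = df["dnam_age"].isna()
    if missing.any():
        logger.warning("excluding %d samples without DNAm age", int(missing.sum()))
        df = df[~missing]
    df["pcar"] = df["dnam_age"] / df["chrono_age"]

    per_patient = {}
    for patient, grp in df.groupby("patient_id"):
        vals = grp["pcar"].to_numpy()
        if len(vals) < 2:
            per_patient[patient] = (0.0, True)
        else:
            rel = (vals.max() - vals.min()) / vals.min()
            per_patient[patient] = (float(rel), bool(rel < homogeneity_bound))
    df["max_pcar_diff"] = df["patient_id"].map(lambda p: per_patient[p][0])
    df["homogeneous"] = df["patient_id"].map(lambda p: per_patient[p][1])
    df["n_patient_samples"] = df.groupby("patient_id")["sample_id"].transform("count")
    return df.reset_index(drop=True)
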