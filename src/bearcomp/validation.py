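"""Model testing against paired-capture isotopic lipid measurements.

Adult bears captured twice provide a measured change in body lipids
(isotopic dilution). Because adults are structurally grown, any length
difference between captures is measurement error, so predictions use the
mean of the two lengths at both timepoints; structural mass then cancels
in the difference and the predicted lipid change reduces to the change in
storage lipids. Predictions are compared to the isotopic change by RMSE,
overall and by subgroup, for the multi-storage model and the
single-storage comparator.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import CompositionParams, InvalidInputError, composition_arrays
from .energy import SingleStorageParams, single_storage_energy, \
    single_storage_structural_mass

RECAPTURE_COLUMNS = ["id", "subpop", "sex", "class", "interval_days",
                     "len1_m", "mass1_kg", "lipid1_kg",
                     "len2_m", "mass2_kg", "lipid2_kg"]


def validate_recaptures(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECAPTURE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"recapture data missing columns {missing}")
    num = ["interval_days", "len1_m", "mass1_kg", "lipid1_kg", "len2_m",
           "mass2_kg", "lipid2_kg"]
    if (df[num] <= 0).any().any():
        raise InvalidInputError("recapture measurements must be positive")
    for i in (1, 2):
        if (df[f"lipid{i}_kg"] >= df[f"mass{i}_kg"]).any():
            raise InvalidInputError("lipid mass must be below total mass")
    return df


def mean_length(record) -> float:
    """Mean straight-line length over the two captures (m)."""
    l1, l2 = record["len1_m"], record["len2_m"]
    if pd.isna(l1) or pd.isna(l2):
        raise InvalidInputError("both capture lengths are required")
    return 0.5 * (float(l1) + float(l2))


def predict_lipid_change(record, p: CompositionParams,
                         muscle_level: str = "avg"):
    """Predicted storage-lipid change O_L(t2) − O_L(t1), kg.

    Uses the mean length at both timepoints with each capture's mass.
    Returns ``(delta, feasible)``; ``delta`` is NaN when either timepoint
    falls below the structural-mass boundary.
    """
    L = mean_length(record)
    sex = record["sex"]
    r1 = composition_arrays(L, float(record["mass1_kg"]), sex, p, muscle_level)
    r2 = composition_arrays(L, float(record["mass2_kg"]), sex, p, muscle_level)
    feasible = bool(r1["feasible"]) and bool(r2["feasible"])
    delta = float(r2["O_L"] - r1["O_L"]) if feasible else np.nan
    return delta, feasible


def single_storage_lipid_change(record, p: SingleStorageParams):
    """Comparator's lipid change: storage change times lipid fraction."""
    L = mean_length(record)
    K = single_storage_structural_mass(L, p)
    m1, m2 = float(record["mass1_kg"]), float(record["mass2_kg"])
    feasible = m1 >= K and m2 >= K
    if not feasible:
        return np.nan, False
    return (m2 - m1) * p.storage_lipid_fraction, True


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean squared error between equal-length vectors (kg)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise InvalidInputError("prediction and observation vectors must "
                                "be non-empty and equally long")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def paired_length_ttest(df: pd.DataFrame):
    """Paired two-sample t test of capture-1 vs capture-2 lengths.

    Returns ``(t, df, p)`` with df = n − 1 and a two-tailed p value.
    """
    l1 = df["len1_m"].to_numpy(float)
    l2 = df["len2_m"].to_numpy(float)
    if len(l1) < 2:
        raise InvalidInputError("at least 2 records required")
    if np.std(l1 - l2, ddof=1) == 0:
        raise InvalidInputError("zero variance of length differences: "
                                "t statistic undefined")
    res = stats.ttest_rel(l1, l2)
    return float(res.statistic), len(l1) - 1, float(res.pvalue)


DEFAULT_SUBGROUPS = {
    "WH males": lambda d: (d["subpop"] == "WH") & (d["sex"] == "M"),
    "WH females": lambda d: (d["subpop"] == "WH") & (d["sex"] == "F"),
    "SB females": lambda d: (d["subpop"] == "SB") & (d["sex"] == "F"),
}


def compare_models(records: pd.DataFrame, multi: CompositionParams,
                   single: SingleStorageParams,
                   subgroups: Optional[dict] = None,
                   exclude_ids: Optional[Iterable[str]] = None,
                   muscle_level: str = "avg") -> dict:
    """RMSE comparison table, overall and per subgroup.

    Non-adult records are rejected (the validation logic attributes lipid
    change to storage lipids, which holds for structurally grown bears).
    Records with an infeasible timepoint under either model are excluded
    and listed, not imputed. When ``exclude_ids`` is given, an
    exclusion-sensitivity block recomputes every row without those ids.
    """
    validate_recaptures(records)
    if (records["class"] != "adult").any():
        bad = records.loc[records["class"] != "adult", "id"].tolist()
        raise InvalidInputError(
            f"validation accepts adult records only; non-adult ids: {bad}")
    subgroups = DEFAULT_SUBGROUPS if subgroups is None else subgroups

    work = records.copy()
    pred_multi, pred_single, feas = [], [], []
    for _, row in work.iterrows():
        dm, fm = predict_lipid_change(row, multi, muscle_level)
        ds, fs = single_storage_lipid_change(row, single)
        pred_multi.append(dm)
        pred_single.append(ds)
        feas.append(fm and fs)
    work["pred_multi_kg"] = pred_multi
    work["pred_single_kg"] = pred_single
    work["obs_kg"] = work["lipid2_kg"] - work["lipid1_kg"]
    work["feasible"] = feas
    excluded_infeasible = work.loc[~work["feasible"], "id"].tolist()
    work = work[work["feasible"]]

    def table(d: pd.DataFrame) -> pd.DataFrame:
        rows = [{"group": "all", "n": len(d),
                 "rmse_multi_vs_isotopic_kg": rmse(d["pred_multi_kg"], d["obs_kg"]),
                 "rmse_single_vs_isotopic_kg": rmse(d["pred_single_kg"], d["obs_kg"]),
                 "rmse_multi_vs_single_kg": rmse(d["pred_multi_kg"], d["pred_single_kg"])}]
        for name, sel in subgroups.items():
            sub = d[sel(d)]
            if len(sub) == 0:
                rows.append({"group": name, "n": 0,
                             "rmse_multi_vs_isotopic_kg": np.nan,
                             "rmse_single_vs_isotopic_kg": np.nan,
                             "rmse_multi_vs_single_kg": np.nan})
                continue
            rows.append({"group": name, "n": len(sub),
                         "rmse_multi_vs_isotopic_kg": rmse(sub["pred_multi_kg"], sub["obs_kg"]),
                         "rmse_single_vs_isotopic_kg": rmse(sub["pred_single_kg"], sub["obs_kg"]),
                         "rmse_multi_vs_single_kg": rmse(sub["pred_multi_kg"], sub["pred_single_kg"])})
        return pd.DataFrame(rows)

    report = {"rmse": table(work),
              "excluded_infeasible_ids": excluded_infeasible,
              "predictions": work}
    if exclude_ids is not None:
        exclude_ids = list(exclude_ids)
        kept = work[~work["id"].isin(exclude_ids)]
        if len(kept) == 0:
            raise InvalidInputError("exclusion removes every record")
        report["exclusion_sensitivity"] = table(kept)
        report["excluded_ids"] = exclude_ids
    return report
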