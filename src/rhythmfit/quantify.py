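"""qPCR relative quantification: ddCt, per-replicate mean normalization, summaries.

Ct tables are long-format :class:`pandas.DataFrame` objects with columns
``cell_line, gene, time_h, replicate, experiment, ct``; one gene is the
designated reference. Relative expression is ``base**(-ddCt)`` with the
calibrator chosen per replicate (t = 0 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timecourse import TimeCourse

__all__ = [
    "CT_COLUMNS",
    "ReplicateSummary",
    "collapse_technical",
    "relative_expression_ddct",
    "mean_normalize",
    "summarize_replicates",
]

CT_COLUMNS = ("cell_line", "gene", "time_h", "replicate", "experiment", "ct")

#: per-replicate key inside one cell line
_REP_KEY = ["replicate", "experiment"]


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    if not np.isfinite(ct["ct"].to_numpy(float)).all():
        raise ValueError("all Ct values must be finite")
    return ct


def collapse_technical(ct: pd.DataFrame, method: str = "median") -> pd.DataFrame:
    """Collapse technical replicates (duplicate keys) into one Ct per biological replicate."""
    validate_ct_table(ct)
    keys = ["cell_line", "gene", "time_h", "replicate", "experiment"]
    agg = {"median": "median", "mean": "mean"}.get(method)
    if agg is None:
        raise ValueError(f"unknown collapse method {method!r}")
    return ct.groupby(keys, as_index=False)["ct"].agg(agg)


def relative_expression_ddct(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str | float = "t0",
    efficiency_base: float = 2.0,
) -> TimeCourse:
    """Relative expression of ``target`` vs ``reference`` via the ddCt method.

    Per (time, replicate): ``dCt = Ct_target - Ct_reference``;
    ``ddCt = dCt - dCt_calibrator``; value = ``base**(-ddCt)``.

    ``calibrator`` is either ``"t0"`` (that replicate's dCt at the earliest
    time point), ``"mean"`` (that replicate's mean dCt over time) or a fixed
    numeric dCt.
    """
    validate_ct_table(ct)
    cell_lines = ct["cell_line"].unique()
    if len(cell_lines) != 1:
        raise ValueError(
            f"Ct table must hold a single cell line, got {sorted(map(str, cell_lines))}; "
            "group by cell_line first"
        )
    cell_line = cell_lines[0]

    tgt = ct[ct["gene"] == target]
    ref = ct[ct["gene"] == reference]
    if tgt.empty:
        raise ValueError(f"no rows for target gene {target!r}")
    if ref.empty:
        raise ValueError(f"no rows for reference gene {reference!r}")

    keys = ["time_h", "replicate", "experiment"]
    merged = tgt.merge(ref, on=keys, how="left", suffixes=("_tgt", "_ref"))
    orphan = merged["ct_ref"].isna()
    if orphan.any():
        row = merged.loc[orphan.idxmax()]
        raise ValueError(
            "no reference-gene Ct for row "
            f"(cell_line={cell_line!r}, gene={target!r}, time_h={row['time_h']}, "
            f"replicate={row['replicate']!r}, experiment={row['experiment']!r})"
        )

    merged["dct"] = merged["ct_tgt"] - merged["ct_ref"]
    if isinstance(calibrator, (int, float)) and not isinstance(calibrator, bool):
        merged["dct_cal"] = float(calibrator)
    elif calibrator == "t0":
        t0 = merged["time_h"].min()
        cal = merged[merged["time_h"] == t0].set_index(_REP_KEY)["dct"]
        idx = pd.MultiIndex.from_frame(merged[_REP_KEY])
        merged["dct_cal"] = cal.reindex(idx).to_numpy()
        if merged["dct_cal"].isna().any():
            bad = merged.loc[merged["dct_cal"].isna(), _REP_KEY].iloc[0]
            raise ValueError(
                f"replicate {tuple(bad)} has no t = {t0} observation to calibrate against"
            )
    elif calibrator == "mean":
        merged["dct_cal"] = merged.groupby(_REP_KEY)["dct"].transform("mean")
    else:
        raise ValueError(f"unknown calibrator rule {calibrator!r}")

    merged["value"] = float(efficiency_base) ** -(merged["dct"] - merged["dct_cal"])
    return _long_to_timecourse(merged, (cell_line, target))


def _long_to_timecourse(df: pd.DataFrame, label: tuple) -> TimeCourse:
    times = np.sort(df["time_h"].unique())
    reps = sorted(set(map(tuple, df[_REP_KEY].itertuples(index=False))))
    values = np.full((times.size, len(reps)), np.nan)
    t_pos = {t: i for i, t in enumerate(times)}
    r_pos = {r: j for j, r in enumerate(reps)}
    for row in df.itertuples(index=False):
        values[t_pos[row.time_h], r_pos[(row.replicate, row.experiment)]] = row.value
    return TimeCourse(label, times, values, {"replicates": reps})


def mean_normalize(tc: TimeCourse) -> TimeCourse:
    """Divide each replicate by its own mean over its present time points."""
    with np.errstate(invalid="ignore"):
        means = np.nanmean(tc.values, axis=0)
    if np.any(~np.isfinite(means)):
        raise ValueError("replicate with no present values cannot be normalized")
    if np.any(means <= 0):
        bad = np.nonzero(means <= 0)[0].tolist()
        raise ValueError(f"non-positive replicate means at columns {bad}")
    return tc.with_values(tc.values / means, normalized="per-replicate mean")


@dataclass
class ReplicateSummary:
    """Per-time-point median/variance/count across replicates."""

    times: np.ndarray
    median: np.ndarray
    variance: np.ndarray  # NaN where undefined (n == 1)
    n: np.ndarray

    @property
    def variance_defined(self) -> np.ndarray:
        return self.n > 1


def summarize_replicates(tc: TimeCourse) -> ReplicateSummary:
    """Median, unbiased sample variance and replicate count per time point."""
    n = tc.counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        median = np.nanmedian(tc.values, axis=1)
        variance = np.full(tc.n_times, np.nan)
        multi = n > 1
        if multi.any():
            variance[multi] = np.nanvar(tc.values[multi], axis=1, ddof=1)
    return ReplicateSummary(tc.times.copy(), median, variance, n)
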