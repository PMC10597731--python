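"""Mid-L3 vs non-mid-L3 variability statistics and the sex comparison.

The central statistic is the per-patient *average percent difference*:
for one body-composition measure, the mean over all non-mid slices of
``|(slice value - mid value) / mid value| * 100``.  It quantifies how
much a measurement taken anywhere across the L3 span deviates from the
conventional single mid-L3 measurement.

Cohort distributions are summarised as median (IQR) and compared
between sexes with a two-sided Mann-Whitney U test.  The test has an
*exact* mode that evaluates the full permutation distribution of U
(ties handled via midranks, evaluated by subset-sum dynamic programming
— feasible for the small groups where exactness matters) and an
*asymptotic* mode using the tie-corrected normal approximation with
continuity correction; ``auto`` picks exact for small groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import InsufficientDataError, InvalidInputError
from .metrics import CompositionMeasure
from .segmentation import TISSUES

#: The six per-patient variability measures, in reporting order.
MEASURES = [f"{t}_{k}" for t in TISSUES for k in ("area", "radiodensity")]

#: Group sizes up to which ``mode="auto"`` uses the exact permutation test.
EXACT_MIN_N, EXACT_MAX_N = 8, 12


@dataclass
class VariabilityRecord:
    """Average percent difference per measure for one patient (NaN = undefined)."""

    patient_id: str
    sex: str
    values: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortSummary:
    """One row of a cohort summary table (measure x group)."""

    measure: str
    group: str  # "all" | "female" | "male"
    n: int
    median: float
    iqr_low: float
    iqr_high: float
    p_value: float  # male-vs-female Mann-Whitney p for this measure
    significant: bool


@dataclass
class MannWhitneyResult:
    u: float
    p_value: float
    mode_used: str


def avg_percent_difference(mid_value: float, other_values: Iterable[float]) -> float:
    """Mean of ``|(v - mid) / mid| * 100`` over the non-mid values.

    Returns NaN (the undefined marker, recorded rather than raised) when
    the mid value is 0 or undefined, or when no defined non-mid value
    remains — a ratio to a zero or missing baseline has no meaning.
    """
    others = [v for v in other_values if v is not None and not math.isnan(v)]
    if mid_value is None or math.isnan(mid_value) or mid_value == 0 or not others:
        return math.nan
    mid = float(mid_value)
    return float(np.mean([abs((v - mid) / mid) for v in others]) * 100.0)


def cohort_summary(values: Iterable[float]) -> tuple[float, tuple[float, float]]:
    """Median and (25th, 75th) percentiles, linear interpolation, NaNs dropped."""
    vals = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("no defined values to summarise")
    q25, med, q75 = np.percentile(vals, [25, 50, 75])
    return float(med), (float(q25), float(q75))


def _exact_u_distribution(doubled_ranks: np.ndarray, n_a: int) -> np.ndarray:
    """Counts of subset rank-sums (in doubled-rank units) over all
    ``C(N, n_a)`` assignments of the pooled sample to group A.

    dp[k, s] = number of k-subsets of the processed items with doubled
    rank-sum s; O(N * n_a * S) time, exact in integer arithmetic.
    """
    total = int(doubled_ranks.sum())
    dp = np.zeros((n_a + 1, total + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in doubled_ranks:
        r = int(r)
        for k in range(n_a, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[n_a]


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], mode: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Reports U for the first group (number of (a, b) pairs won by ``a``
    plus half the ties).  ``exact`` enumerates the permutation
    distribution of U over all group assignments of the pooled values;
    ``asymptotic`` uses the normal approximation with tie-corrected
    variance and 0.5 continuity correction; ``auto`` selects exact when
    ``min(n) <= 8`` and ``max(n) <= 12``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise InvalidInputError("NaN values must be removed before testing")
    if mode not in ("exact", "asymptotic", "auto"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    n_a, n_b = a.size, b.size
    if mode == "auto":
        mode = "exact" if min(n_a, n_b) <= EXACT_MIN_N and max(n_a, n_b) <= EXACT_MAX_N else "asymptotic"

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r_a = float(ranks[:n_a].sum())
    u = r_a - n_a * (n_a + 1) / 2.0  # = #(a > b) + ties/2
    mu = n_a * n_b / 2.0

    if mode == "exact":
        doubled = np.rint(2 * ranks).astype(np.int64)
        dist = _exact_u_distribution(doubled, n_a)
        # doubled U for a subset with doubled rank-sum s: s - n_a(n_a+1)
        s_axis = np.arange(dist.shape[0], dtype=np.int64)
        u2 = s_axis - n_a * (n_a + 1)
        obs_dev = abs(int(round(2 * u)) - int(round(2 * mu)))
        extreme = np.abs(u2 - int(round(2 * mu))) >= obs_dev
        p = float(int(dist[extreme].sum()) / int(dist.sum()))
    else:
        N = n_a + n_b
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
        var = n_a * n_b / 12.0 * ((N + 1) - tie_term)
        if var <= 0 or u == mu:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return MannWhitneyResult(u=float(u), p_value=p, mode_used=mode)


def build_variability_records(
    measures: "pd.DataFrame | Mapping[str, Sequence[CompositionMeasure]]",
    sex_by_patient: Mapping[str, str] | None = None,
) -> list[VariabilityRecord]:
    """One :class:`VariabilityRecord` per patient from per-slice measures.

    Accepts either the tidy long-format frame produced by
    :func:`l3comp.metrics.measures_to_frame` plus a ``sex`` column (or a
    ``sex_by_patient`` mapping), or a mapping patient_id -> list of
    :class:`CompositionMeasure` with ``sex_by_patient`` supplied.
    Each patient needs exactly one mid slice and at least one non-mid
    slice; undefined inputs propagate to NaN per measure.
    """
    if not isinstance(measures, pd.DataFrame):
        rows = []
        for pid, ms in measures.items():
            for m in ms:
                for t in TISSUES:
                    rows.append(
                        {
                            "patient_id": pid,
                            "slice_index": m.slice_index,
                            "is_mid": m.is_mid,
                            "tissue": t,
                            "area_cm2": m.area_cm2[t],
                            "radiodensity_hu": m.radiodensity_hu[t],
                        }
                    )
        measures = pd.DataFrame(rows)

    df = measures
    records = []
    for pid, g in df.groupby("patient_id", sort=True):
        if sex_by_patient is not None:
            sex = sex_by_patient[pid]
        elif "sex" in g.columns:
            sex = str(g["sex"].iloc[0])
        else:
            raise InvalidInputError("sex not provided (no 'sex' column or mapping)")
        n_mid = g.loc[g["is_mid"], "slice_index"].nunique()
        n_other = g.loc[~g["is_mid"], "slice_index"].nunique()
        if n_mid != 1:
            raise InvalidInputError(f"patient {pid}: expected exactly 1 mid slice, got {n_mid}")
        if n_other < 1:
            raise InsufficientDataError(f"patient {pid}: no non-mid slices")
        rec = VariabilityRecord(patient_id=str(pid), sex=sex)
        for t in TISSUES:
            gt = g[g["tissue"] == t]
            for kind, col in (("area", "area_cm2"), ("radiodensity", "radiodensity_hu")):
                mid_vals = gt.loc[gt["is_mid"], col].to_numpy(dtype=float)
                other_vals = gt.loc[~gt["is_mid"], col].to_numpy(dtype=float)
                mid = float(mid_vals[0]) if mid_vals.size else math.nan
                rec.values[f"{t}_{kind}"] = avg_percent_difference(mid, other_vals)
        records.append(rec)
    return records


def compare_groups(
    measure: str,
    female_values: Sequence[float],
    male_values: Sequence[float],
    mode: str = "auto",
    alpha: float = 0.05,
) -> list[CohortSummary]:
    """All / female / male summary rows plus the male-vs-female p for one measure."""
    f = [v for v in female_values if not math.isnan(v)]
    m = [v for v in male_values if not math.isnan(v)]
    if f and m:
        p = mann_whitney(m, f, mode=mode).p_value
    else:
        p = math.nan
    rows = []
    for group, vals in (("all", f + m), ("female", f), ("male", m)):
        if vals:
            med, (lo, hi) = cohort_summary(vals)
        else:
            med = lo = hi = math.nan
        rows.append(
            CohortSummary(
                measure=measure,
                group=group,
                n=len(vals),
                median=med,
                iqr_low=lo,
                iqr_high=hi,
                p_value=p,
                significant=bool(p < alpha) if not math.isnan(p) else False,
            )
        )
    return rows


def sex_comparison(
    records: Sequence[VariabilityRecord], mode: str = "auto", alpha: float = 0.05
) -> list[CohortSummary]:
    """Summary of all six variability measures by sex with Mann-Whitney p.

    Undefined (NaN) values are excluded per measure, not per patient,
    so one zero-VAT mid slice does not shrink the muscle sample.
    """
    sexes = {r.sex for r in records}
    if not {"female", "male"} <= sexes:
        raise InsufficientDataError(f"both sexes required, got {sorted(sexes)}")
    out: list[CohortSummary] = []
    for measure in MEASURES:
        f = [r.values.get(measure, math.nan) for r in records if r.sex == "female"]
        m = [r.values.get(measure, math.nan) for r in records if r.sex == "male"]
        out.extend(compare_groups(measure, f, m, mode=mode, alpha=alpha))
    return out


def summaries_to_frame(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    """Summary rows as a flat table (measure, group, n, median, IQR, p)."""
    return pd.DataFrame(
        [
            {
                "measure": s.measure,
                "group": s.group,
                "n": s.n,
                "median": s.median,
                "iqr_low": s.iqr_low,
                "iqr_high": s.iqr_high,
                "p_value": s.p_value,
                "significant": s.significant,
            }
            for s in summaries
        ]
    )
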