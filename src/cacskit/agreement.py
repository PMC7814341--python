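"""Automatic-vs-manual agreement battery for calcium-score method comparison.

Implements the statistics used to validate an automatic scorer against a
manual (ground-truth) reading: two-way random-effects absolute-agreement
single-measure intraclass correlation (ICC(2,1)) with its F-based 95% CI,
Bland-Altman limits of agreement, paired t-tests on the score differences,
McNemar tests on paired calcified/not-calcified flags, Wilcoxon signed-rank
tests on ordinal CAC-DRS categories, voxelwise per-vessel F1, and the
CAC-DRS reclassification cross-table.

Conventions worth knowing:

* McNemar uses the exact two-sided binomial test when the discordant count
  b+c <= 25 and the chi-square test with continuity correction otherwise;
  b+c = 0 returns p = 1.0 by convention.
* Wilcoxon drops zero differences (classical convention) and uses the exact
  null for <= 25 nonzero pairs. ``method="approx"`` switches to the normal
  approximation without continuity correction, the convention some clinical
  statistics packages apply even for a single nonzero pair (where it yields
  p = 0.317 rather than the exact p = 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    CORONARY_LABELS,
    VESSEL_NAMES,
    VesselLabelMask,
    GeometryError,
)

A_LEVELS = ("A0", "A1", "A2", "A3")
N_LEVELS = ("N0", "N1", "N2", "N3", "N4")


class DegenerateDataError(ValueError):
    """The requested statistic is undefined on this input (e.g. zero variance)."""


@dataclass
class PairedScores:
    """Paired automatic (x) and manual (y) values for one measure and level."""

    case_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    measure: str = ""
    level: str = "Total"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.case_ids) != self.x.size:
            raise ValueError("case_ids length must match the value arrays")
        if self.x.size < 2:
            raise ValueError("paired comparison needs at least 2 cases")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("paired scores must be finite")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def differences(self) -> np.ndarray:
        return self.x - self.y


@dataclass
class CategoricalPairs:
    """Paired categorical readings (binary flags or ordinal categories)."""

    case_ids: list[str]
    auto: list
    manual: list

    def __post_init__(self) -> None:
        if not (len(self.case_ids) == len(self.auto) == len(self.manual)):
            raise ValueError("case_ids, auto and manual must have equal length")


def icc(pairs: PairedScores) -> dict:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Returns the estimate and the F-based 95% confidence interval. Requires
    n >= 3 and nonzero between-subject variance.
    """
    if pairs.n < 3:
        raise DegenerateDataError("ICC needs at least 3 paired cases")
    stacked = np.concatenate([pairs.x, pairs.y])
    if np.allclose(stacked, stacked[0]):
        raise DegenerateDataError("ICC undefined on constant data (zero variance)")
    import pingouin as pg  # deferred: pingouin import is slow

    long = pd.DataFrame({
        "case": np.tile(np.arange(pairs.n), 2),
        "rater": np.repeat(["auto", "manual"], pairs.n),
        "value": stacked,
    })
    import warnings

    with warnings.catch_warnings():
        # perfect agreement gives MSE = 0; pingouin then divides by zero
        # computing the F statistic and CI, which is handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(data=long, targets="case", raters="rater",
                                   ratings="value")
    table = table.set_index("Type")
    # absolute-agreement single-measure row; label differs across versions
    key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[key]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    estimate = float(row["ICC"])
    ci = tuple(float(v) if np.isfinite(v) else None for v in row[ci_col])
    if ci == (None, None) and np.isclose(estimate, 1.0):
        ci = (1.0, 1.0)  # zero residual variance: agreement is exact
    return {"icc": estimate, "ci95": ci, "n": pairs.n}


def bland_altman(pairs: PairedScores) -> dict:
    """Mean difference, sample SD, 95% limits of agreement, and the number of
    differences strictly outside the limits."""
    d = pairs.differences
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff
    n_outside = int(np.sum((d < loa_low) | (d > loa_high)))
    return {
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "loa_low": loa_low,
        "loa_high": loa_high,
        "n_outside": n_outside,
        "n": pairs.n,
    }


def paired_t(pairs: PairedScores) -> tuple[float, float]:
    """Two-sided paired t-test on the automatic-minus-manual differences."""
    d = pairs.differences
    if np.allclose(d, d[0]) and np.isclose(d.std(ddof=1), 0.0):
        raise DegenerateDataError(
            "paired t-test undefined: zero variance of differences"
        )
    res = stats.ttest_rel(pairs.x, pairs.y)
    return float(res.statistic), float(res.pvalue)


def mcnemar(binary: CategoricalPairs) -> dict:
    """McNemar test on paired binary flags.

    b counts auto-positive / manual-negative pairs, c the reverse. Exact
    two-sided binomial p for b + c <= 25, chi-square with continuity
    correction otherwise; p = 1.0 when there are no discordant pairs.
    """
    auto = np.asarray(binary.auto, dtype=bool)
    manual = np.asarray(binary.manual, dtype=bool)
    b = int(np.sum(auto & ~manual))
    c = int(np.sum(~auto & manual))
    if b + c == 0:
        return {"b": b, "c": c, "p": 1.0, "method": "none-discordant"}
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    a = int(np.sum(auto & manual))
    d = int(np.sum(~auto & ~manual))
    table = [[a, b], [c, d]]
    exact = b + c <= 25
    res = sm_mcnemar(table, exact=exact, correction=True)
    return {
        "b": b,
        "c": c,
        "p": min(1.0, float(res.pvalue)),
        "method": "exact-binomial" if exact else "chi2-cc",
    }


_ORDINAL_CODES = {**{a: i for i, a in enumerate(A_LEVELS)},
                  **{n: i for i, n in enumerate(N_LEVELS)}}


def _encode_ordinal(values: list) -> np.ndarray:
    out = []
    for v in values:
        if isinstance(v, str):
            if v not in _ORDINAL_CODES:
                raise ValueError(f"unknown category {v!r}")
            out.append(_ORDINAL_CODES[v])
        else:
            out.append(int(v))
    return np.asarray(out, dtype=np.float64)


def wilcoxon_signed_rank(ordinal: CategoricalPairs, method: str = "exact"
                         ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on ordinal category differences.

    Zero differences are dropped (classical convention). ``method="exact"``
    enumerates the null for <= 25 nonzero pairs; ``method="approx"`` uses the
    normal approximation without continuity correction. All-zero differences
    return (0.0, 1.0) with a warning.
    """
    if method not in ("exact", "approx"):
        raise ValueError("method must be 'exact' or 'approx'")
    d = _encode_ordinal(ordinal.auto) - _encode_ordinal(ordinal.manual)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        import warnings

        warnings.warn("all category differences are zero; p = 1.0 by "
                      "convention", UserWarning, stacklevel=2)
        return 0.0, 1.0
    if method == "exact" and nonzero.size <= 25:
        scipy_method = "exact"
    else:
        scipy_method = "approx"
    res = stats.wilcoxon(nonzero, zero_method="wilcox", correction=False,
                         alternative="two-sided", method=scipy_method)
    return float(res.statistic), float(res.pvalue)


def f1_per_vessel(pred: VesselLabelMask, truth: VesselLabelMask) -> dict:
    """Voxelwise F1 (= Dice) per coronary label over the whole volume.

    A label absent from both masks has no defined F1 and is reported as None.
    """
    if pred.shape != truth.shape:
        raise GeometryError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}"
        )
    out: dict[str, float | None] = {}
    for vessel in CORONARY_LABELS:
        p = pred.labels == vessel
        t = truth.labels == vessel
        tp = int(np.sum(p & t))
        fp = int(np.sum(p & ~t))
        fn = int(np.sum(~p & t))
        if tp + fp + fn == 0:
            out[VESSEL_NAMES[vessel]] = None
        else:
            out[VESSEL_NAMES[vessel]] = 2 * tp / (2 * tp + fp + fn)
    return out


def confuser_leak_fraction(pred: VesselLabelMask, truth: VesselLabelMask) -> float | None:
    """Fraction of true non-coronary (label-5) voxels predicted as coronary."""
    from .core_io import NON_CORONARY

    confuser = truth.labels == NON_CORONARY
    n = int(confuser.sum())
    if n == 0:
        return None
    leaked = int(np.isin(pred.labels[confuser], CORONARY_LABELS).sum())
    return leaked / n


def reclassification_table(ordinal: CategoricalPairs,
                           levels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Automatic-vs-manual category cross-table with marginal counts."""
    auto = list(ordinal.auto)
    manual = list(ordinal.manual)
    if levels is None:
        levels = A_LEVELS if set(auto) | set(manual) <= set(A_LEVELS) else N_LEVELS
    for v in auto + manual:
        if v not in levels:
            raise ValueError(f"category {v!r} not in levels {levels}")
    auto_cat = pd.Categorical(auto, categories=levels)
    manual_cat = pd.Categorical(manual, categories=levels)
    table = pd.crosstab(
        pd.Series(auto_cat, name="automatic"),
        pd.Series(manual_cat, name="manual"),
        dropna=False,
    )
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


# ---------------------------------------------------------------------------
# Full battery over paired score tables

SCORE_MEASURES = ("AS", "VS", "MS")
LEVELS = ("Total", "LM", "LAD", "LCX", "RCA")


def scores_to_long(case_scores: dict[str, dict], provenance: str = "automatic"
                   ) -> pd.DataFrame:
    """Flatten {case_id: CacsResult-dict} into the long CSV layout
    ``case_id, level, measure, value`` (measures AS/VS/MS/NV, A/N as codes)."""
    rows = []
    key_map = {"AS": "agatston", "VS": "volume_mm3", "MS": "mass_mg"}
    for case_id, result in case_scores.items():
        d = result.to_dict() if hasattr(result, "to_dict") else result
        for measure, key in key_map.items():
            for level in LEVELS:
                rows.append((case_id, level, measure, d[key][level]))
        rows.append((case_id, "Total", "NV", d["n_vessels"]))
        for vessel in ("LM", "LAD", "LCX", "RCA"):
            rows.append((case_id, vessel, "CALC",
                         1.0 if vessel in d["calcified_vessels"] else 0.0))
        rows.append((case_id, "Total", "A_CAT",
                     float(A_LEVELS.index(d["a_category"]))))
        rows.append((case_id, "Total", "N_CAT",
                     float(N_LEVELS.index(d["n_category"]))))
    df = pd.DataFrame(rows, columns=["case_id", "level", "measure", "value"])
    df["provenance"] = provenance
    return df


def _pairs_from_long(auto_df: pd.DataFrame, manual_df: pd.DataFrame,
                     measure: str, level: str) -> PairedScores | None:
    a = auto_df[(auto_df.measure == measure) & (auto_df.level == level)]
    m = manual_df[(manual_df.measure == measure) & (manual_df.level == level)]
    merged = a.merge(m, on="case_id", suffixes=("_auto", "_manual"))
    if len(merged) < 2:
        return None
    merged = merged.sort_values("case_id")
    return PairedScores(case_ids=merged.case_id.tolist(),
                        x=merged.value_auto.to_numpy(),
                        y=merged.value_manual.to_numpy(),
                        measure=measure, level=level)


def run_battery(auto_df: pd.DataFrame, manual_df: pd.DataFrame,
                wilcoxon_method: str = "exact") -> dict:
    """The full comparison battery on two long-format score tables.

    For each continuous measure (AS/VS/MS at each level, plus the total
    vessel count NV): ICC(2,1) + CI, Bland-Altman, paired t. Per-vessel
    calcified flags: McNemar. Ordinal CAC-DRS A and N categories: Wilcoxon
    signed-rank and the reclassification table. Degenerate cases (perfect
    agreement) are reported with their conventional values and flagged.
    """
    report: dict = {"continuous": {}, "mcnemar": {}, "cac_drs": {}}
    targets = [(m, lv) for m in SCORE_MEASURES for lv in LEVELS]
    targets.append(("NV", "Total"))
    for measure, level in targets:
        pairs = _pairs_from_long(auto_df, manual_df, measure, level)
        if pairs is None:
            continue
        entry: dict = {"n": pairs.n, "bland_altman": bland_altman(pairs)}
        try:
            entry["icc"] = icc(pairs)
        except DegenerateDataError as exc:
            entry["icc"] = {"icc": None, "note": str(exc)}
        try:
            t_stat, p = paired_t(pairs)
            entry["paired_t"] = {"t": t_stat, "p": p}
        except DegenerateDataError:
            entry["paired_t"] = {"t": 0.0, "p": 1.0,
                                 "note": "identical scores; no-difference convention"}
        report["continuous"][f"{measure}/{level}"] = entry
    for vessel in ("LM", "LAD", "LCX", "RCA"):
        a = auto_df[(auto_df.measure == "CALC") & (auto_df.level == vessel)]
        m = manual_df[(manual_df.measure == "CALC") & (manual_df.level == vessel)]
        merged = a.merge(m, on="case_id", suffixes=("_auto", "_manual"))
        if merged.empty:
            continue
        flags = CategoricalPairs(case_ids=merged.case_id.tolist(),
                                 auto=(merged.value_auto > 0).tolist(),
                                 manual=(merged.value_manual > 0).tolist())
        report["mcnemar"][vessel] = mcnemar(flags) | {
            "n_auto": int(merged.value_auto.sum()),
            "n_manual": int(merged.value_manual.sum()),
        }
    for cat, levels in (("A_CAT", A_LEVELS), ("N_CAT", N_LEVELS)):
        a = auto_df[(auto_df.measure == cat)]
        m = manual_df[(manual_df.measure == cat)]
        merged = a.merge(m, on="case_id", suffixes=("_auto", "_manual"))
        if merged.empty:
            continue
        pairs = CategoricalPairs(
            case_ids=merged.case_id.tolist(),
            auto=[levels[int(v)] for v in merged.value_auto],
            manual=[levels[int(v)] for v in merged.value_manual],
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            stat, p = wilcoxon_signed_rank(pairs, method=wilcoxon_method)
        report["cac_drs"][cat] = {
            "wilcoxon": {"statistic": stat, "p": p},
            "table": reclassification_table(pairs, levels=levels)
            .astype(int).to_dict(),
        }
    return report
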