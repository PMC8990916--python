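"""BMI-stratified cohort analysis of CT dose metrics.

Reproduces the standard clinical dose-audit analysis: patients are
stratified into three BMI groups per region (A/B/C for chest, D/E/F for
abdomen, cut-points <20, 20-24.9, >24.9 kg/m²); each metric is summarized
per group as mean ± sample SD; across-group differences are tested with
one-way ANOVA; and within each group the dose metrics measured on the
same patients (SSDE_ED, SSDE_WED, CTDI_vol) are compared pairwise with a
paired t-test.

The ANOVA F statistic is computed explicitly from between- and
within-group sums of squares so it can be checked against hand-worked
examples; scipy supplies only the F and t tail probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord
from .ssde import ConversionCoefficients, compute_ssde, default_coefficients

__all__ = [
    "assign_bmi_group",
    "group_summary",
    "anova_across_groups",
    "oneway_anova",
    "within_group_metric_test",
    "paired_t",
    "apply_ssde",
    "build_report",
    "GroupComparison",
    "PairedTestResult",
    "SIZE_METRICS",
    "DOSE_METRICS",
    "DOSE_PAIRS",
]

BMI_LOW = 20.0
BMI_HIGH = 24.9

_GROUPS = {"chest": ("A", "B", "C"), "abdomen": ("D", "E", "F")}

SIZE_METRICS = ("ap", "lat", "ed", "f_size_ed", "wed", "f_size_wed")
DOSE_METRICS = ("ctdi_vol", "ssde_ed", "ssde_wed")
DOSE_PAIRS = (
    ("ssde_ed", "ctdi_vol"),
    ("ssde_wed", "ctdi_vol"),
    ("ssde_wed", "ssde_ed"),
)


def assign_bmi_group(bmi: float, region: str) -> str:
    """BMI group label: chest -> A/B/C, abdomen -> D/E/F.

    Cut-points: <20 low, 20-24.9 middle (24.9 inclusive), >24.9 high.
    """
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    try:
        low, mid, high = _GROUPS[region]
    except KeyError:
        raise ValueError(f"region must be chest|abdomen, got {region!r}") from None
    if bmi < BMI_LOW:
        return low
    if bmi <= BMI_HIGH:
        return mid
    return high


def metric_value(record: PatientRecord, metric: str) -> float:
    """Pull one named metric off a patient record."""
    size_fields = {"ap", "lat", "ed", "wed", "roi_area", "mean_hu"}
    if metric == "bmi":
        return record.bmi
    if metric == "ctdi_vol":
        return record.ctdi_vol
    if metric in size_fields:
        v = getattr(record.size, metric)
        if v is None:
            raise ValueError(f"{metric} is unset on record {record.id}")
        return float(v)
    if metric in {"f_size_ed", "f_size_wed", "ssde_ed", "ssde_wed"}:
        if record.ssde is None:
            raise ValueError(
                f"record {record.id} has no SSDE result; run apply_ssde first"
            )
        return float(getattr(record.ssde, metric))
    raise KeyError(f"unknown metric {metric!r}")


def apply_ssde(
    records: Iterable[PatientRecord],
    coeffs: ConversionCoefficients | None = None,
) -> list[PatientRecord]:
    """Fill each record's SSDE bundle in place; returns the list."""
    if coeffs is None:
        coeffs = default_coefficients(32)
    out = list(records)
    for r in out:
        r.ssde = compute_ssde(r.size, r.ctdi_vol, coeffs)
    return out


def _by_group(records: Sequence[PatientRecord], region: str):
    groups: dict[str, list[PatientRecord]] = {g: [] for g in _GROUPS[region]}
    for r in records:
        if r.region == region:
            groups[assign_bmi_group(r.bmi, region)].append(r)
    return groups


def group_summary(
    records: Sequence[PatientRecord], metric: str, region: str | None = None
) -> pd.DataFrame:
    """Per-BMI-group (n, mean, SD) table for one metric.

    SD is the sample estimator (n-1 denominator); empty groups are
    reported with n=0 and NaN statistics.
    """
    if region is None:
        regions = sorted({r.region for r in records})
        if len(regions) != 1:
            raise ValueError(
                "records span multiple regions; pass region= explicitly"
            )
        region = regions[0]
    rows = []
    for label, members in _by_group(records, region).items():
        vals = np.array([metric_value(r, metric) for r in members])
        rows.append(
            {
                "group": label,
                "n": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def oneway_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA from explicit sums of squares.

    F = (SS_between / (k-1)) / (SS_within / (N-k)); the p-value is the
    upper tail of the F(k-1, N-k) distribution.  Degenerate case (zero
    within-group variance everywhere and equal means) returns (0.0, 1.0).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need >=2 groups with >=2 observations each")
    n_tot = sum(len(g) for g in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b = len(arrays) - 1
    df_w = n_tot - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def anova_across_groups(
    records: Sequence[PatientRecord], metric: str, region: str | None = None
) -> tuple[float, float]:
    """Across-BMI-group one-way ANOVA of one metric; returns (F, p)."""
    if region is None:
        region = records[0].region
    groups = [
        np.array([metric_value(r, metric) for r in members])
        for members in _by_group(records, region).values()
        if len(members) >= 2
    ]
    return oneway_anova(groups)


@dataclass(frozen=True)
class PairedTestResult:
    """Paired (or Welch two-sample) t-test outcome for one metric pair."""

    t: float
    p: float
    mean_difference: float
    n: int
    tied: bool = False  # all per-patient differences exactly zero
    paired: bool = True


def paired_t(diff: np.ndarray) -> PairedTestResult:
    """Paired t-test on a difference vector (first metric minus second)."""
    diff = np.asarray(diff, dtype=float)
    n = len(diff)
    if n < 2:
        raise ValueError("need >=2 paired observations")
    sd = diff.std(ddof=1)
    if sd == 0.0:
        return PairedTestResult(
            t=0.0, p=1.0, mean_difference=float(diff.mean()), n=n, tied=True
        )
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return PairedTestResult(
        t=float(t), p=p, mean_difference=float(diff.mean()), n=n
    )


def within_group_metric_test(
    records: Sequence[PatientRecord],
    metric_pair: tuple[str, str],
    paired: bool = True,
) -> PairedTestResult:
    """Compare two metrics measured on the same patients of one group.

    Paired by default (the metrics share patients); the unpaired Welch
    variant is available for sensitivity checks.  t sign convention:
    first metric minus second.
    """
    first, second = metric_pair
    a = np.array([metric_value(r, first) for r in records])
    b = np.array([metric_value(r, second) for r in records])
    if paired:
        return paired_t(a - b)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return PairedTestResult(
        t=float(t), p=float(p), mean_difference=float(a.mean() - b.mean()),
        n=len(a), paired=False,
    )


@dataclass
class GroupComparison:
    """Tables-1-to-4 style analysis bundle for one region.

    ``size_table``/``dose_table`` hold per-group mean ± SD columns;
    ``anova`` maps metric -> (F, p) across groups; ``within`` maps
    (group label, metric pair) -> paired test result.
    """

    region: str
    size_table: pd.DataFrame
    dose_table: pd.DataFrame
    anova: dict[str, tuple[float, float]] = field(default_factory=dict)
    within: dict[tuple[str, tuple[str, str]], PairedTestResult] = field(
        default_factory=dict
    )
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    def significant(self, metric: str) -> bool:
        return metric in self.anova and self.anova[metric][1] < self.alpha


def _summary_frame(
    records: Sequence[PatientRecord], metrics: Sequence[str], region: str
) -> pd.DataFrame:
    frames = {}
    for m in metrics:
        s = group_summary(records, m, region=region)
        frames[m] = s[["mean", "sd"]]
        ns = s["n"]
    out = pd.concat(frames, axis=1)
    out.insert(0, ("n", ""), ns)
    return out


def build_report(
    records: Sequence[PatientRecord],
    alpha: float = 0.05,
    paired: bool = True,
    bonferroni: bool = False,
) -> dict[str, GroupComparison]:
    """Run the full group analysis; one :class:`GroupComparison` per region.

    Records must already carry SSDE results (see :func:`apply_ssde`).
    No multiple-comparison correction is applied by default; pass
    ``bonferroni=True`` to divide alpha by the number of within-group
    pairs.  An empty cohort yields an empty dict; a region with missing
    groups gets its tests skipped with a note.
    """
    report: dict[str, GroupComparison] = {}
    eff_alpha = alpha / len(DOSE_PAIRS) if bonferroni else alpha
    for region in sorted({r.region for r in records}):
        regional = [r for r in records if r.region == region]
        gc = GroupComparison(
            region=region,
            size_table=_summary_frame(regional, SIZE_METRICS, region),
            dose_table=_summary_frame(regional, DOSE_METRICS, region),
            alpha=eff_alpha,
        )
        if bonferroni:
            gc.notes.append(
                f"Bonferroni correction on within-group pairs: alpha={eff_alpha:.4f}"
            )
        groups = _by_group(regional, region)
        testable = {g: m for g, m in groups.items() if len(m) >= 2}
        if len(testable) < 2:
            gc.notes.append(
                f"{region}: fewer than two groups with n>=2; "
                "across-group tests skipped"
            )
        else:
            if len(testable) < len(groups):
                missing = sorted(set(groups) - set(testable))
                gc.notes.append(
                    f"{region}: group(s) {missing} too small; excluded from ANOVA"
                )
            for metric in (*SIZE_METRICS, *DOSE_METRICS):
                gc.anova[metric] = oneway_anova(
                    [
                        np.array([metric_value(r, metric) for r in m])
                        for m in testable.values()
                    ]
                )
        for label, members in testable.items():
            for pair in DOSE_PAIRS:
                gc.within[(label, pair)] = within_group_metric_test(
                    members, pair, paired=paired
                )
        report[region] = gc
    return report


def render_text(report: dict[str, GroupComparison]) -> str:
    """Plain-text rendering of the report tables with significance marks."""
    lines: list[str] = []
    for region, gc in report.items():
        for name, table, metrics in (
            ("size metrics", gc.size_table, SIZE_METRICS),
            ("dose metrics", gc.dose_table, DOSE_METRICS),
        ):
            lines.append(f"== {region}: {name} (mean ± SD; * = ANOVA p < "
                         f"{gc.alpha:g} across groups) ==")
            header = ["group", "n"] + [
                m + ("*" if gc.significant(m) else "") for m in metrics
            ]
            lines.append("\t".join(header))
            for label, row in table.iterrows():
                cells = [str(label), str(int(row[("n", "")]))]
                for m in metrics:
                    mean, sd = row[(m, "mean")], row[(m, "sd")]
                    cells.append(
                        "-" if np.isnan(mean) else f"{mean:.2f} ± {sd:.2f}"
                    )
                lines.append("\t".join(cells))
            lines.append("")
        if gc.within:
            lines.append(f"== {region}: within-group paired comparisons ==")
            for (label, (m1, m2)), res in gc.within.items():
                star = "*" if res.p < gc.alpha else ""
                lines.append(
                    f"{label}: {m1} vs {m2}: t={res.t:.3f} p={res.p:.4g}{star}"
                )
            lines.append("")
        for note in gc.notes:
            lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"
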