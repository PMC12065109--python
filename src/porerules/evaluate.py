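"""Imputation-quality and rule-stability metrics.

Model-vs-model comparison on trained / imputed / all k-mer subsets, matched
shift errors between a ground-truth and a derived rule set, and the
flanking-base ΔC summaries used to visualize context effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from scipy import stats

from .delta_rules import DeltaTable, Rule, RuleSet
from .model_io import CANONICAL_BASES, KmerModel, ModificationScheme

__all__ = [
    "ComparisonReport",
    "RecoveryReport",
    "compare_models",
    "rule_recovery",
    "neighbor_summary",
    "write_report_tsv",
]


@dataclass
class ComparisonReport:
    n: int
    pearson_r: float
    rmse: float
    max_abs_diff: float
    subset_label: str


def _rule_key(rule: Rule) -> tuple:
    return (rule.mod_position, rule.kind, rule.pattern_position, rule.pattern_base)


@dataclass
class RecoveryReport:
    """Per-rule matched shift errors plus rules present in only one set.

    Rules are matched on (position, kind, flank position, flank base);
    shifts of re-selected patterns with the same key are summed before
    matching.
    """

    matched: dict[tuple, tuple[float, float]] = field(default_factory=dict)
    only_in_truth: list[tuple] = field(default_factory=list)
    only_in_derived: list[tuple] = field(default_factory=list)

    @property
    def shift_errors(self) -> dict[tuple, float]:
        return {key: abs(t - d) for key, (t, d) in self.matched.items()}

    @property
    def max_shift_error(self) -> float:
        errs = self.shift_errors
        return max(errs.values()) if errs else 0.0

    @property
    def all_matched(self) -> bool:
        return not self.only_in_truth and not self.only_in_derived


def compare_models(
    a: KmerModel,
    b: KmerModel,
    subset: Literal["trained", "imputed", "all"] = "all",
    trained: Iterable[str] | None = None,
    canonical: KmerModel | None = None,
    scheme: ModificationScheme | None = None,
) -> ComparisonReport:
    """Agreement statistics between two tables on a k-mer subset.

    ``subset="all"`` compares every shared modified k-mer; ``"trained"`` /
    ``"imputed"`` restrict to shared modified k-mers inside / outside the
    ``trained`` inventory.  With ``canonical`` given, comparison happens in
    ΔC space (level minus canonical-counterpart level) instead of raw
    levels; the two are offset by a k-mer-dependent constant, so Pearson r
    generally differs between the spaces.
    """
    canon = set(CANONICAL_BASES)
    shared = sorted(set(a.entries) & set(b.entries))
    shared = [km for km in shared if not set(km) <= canon]
    if subset == "trained":
        if trained is None:
            raise ValueError("subset='trained' requires the trained inventory")
        shared = [km for km in shared if km in set(trained)]
    elif subset == "imputed":
        if trained is None:
            raise ValueError("subset='imputed' requires the trained inventory")
        shared = [km for km in shared if km not in set(trained)]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if not shared:
        raise ValueError(f"no shared modified k-mers on subset {subset!r}")

    xa = np.array([a.level(km) for km in shared])
    xb = np.array([b.level(km) for km in shared])
    if canonical is not None:
        # ΔC space: subtract each k-mer's canonical counterpart level.
        if scheme is None:
            raise ValueError("ΔC-space comparison requires the modification scheme")
        ref = np.empty_like(xa)
        for i, km in enumerate(shared):
            counterpart = scheme.canonicalize(km)
            if counterpart not in canonical.entries:
                raise KeyError(f"no canonical counterpart for {km!r}")
            ref[i] = canonical.level(counterpart)
        xa = xa - ref
        xb = xb - ref

    diff = xa - xb
    rmse = float(np.sqrt(np.mean(diff**2)))
    max_abs = float(np.max(np.abs(diff)))
    if len(shared) < 2:
        r = math.nan
    elif np.allclose(xa, xb):
        r = 1.0
    elif np.std(xa) == 0 or np.std(xb) == 0:
        r = math.nan
    else:
        r = float(stats.pearsonr(xa, xb).statistic)
    return ComparisonReport(
        n=len(shared), pearson_r=r, rmse=rmse, max_abs_diff=max_abs, subset_label=subset
    )


def rule_recovery(truth: RuleSet, derived: RuleSet) -> RecoveryReport:
    """Match two rule sets on rule identity and report shift errors."""
    if truth.scheme != derived.scheme or truth.k != derived.k:
        raise ValueError("rule sets have incompatible scheme or k")
    t_shifts: dict[tuple, float] = {}
    for rule in truth.rules:
        t_shifts[_rule_key(rule)] = t_shifts.get(_rule_key(rule), 0.0) + rule.shift
    d_shifts: dict[tuple, float] = {}
    for rule in derived.rules:
        d_shifts[_rule_key(rule)] = d_shifts.get(_rule_key(rule), 0.0) + rule.shift
    report = RecoveryReport()
    for key in sorted(t_shifts, key=str):
        if key in d_shifts:
            report.matched[key] = (t_shifts[key], d_shifts[key])
        else:
            report.only_in_truth.append(key)
    for key in sorted(d_shifts, key=str):
        if key not in t_shifts:
            report.only_in_derived.append(key)
    return report


def neighbor_summary(delta: DeltaTable, offset: int) -> dict[str, dict[str, float]]:
    """Median ΔC grouped by the base ``offset`` positions from the
    modification (e.g. offset −1 groups NXNMGN-style flanks)."""
    if offset == 0:
        raise ValueError("offset must be non-zero")
    groups: dict[str, list[float]] = {}
    for rec in delta.records:
        pos = rec.mod_position + offset  # 1-based
        if not 1 <= pos <= delta.k:
            continue
        groups.setdefault(rec.kmer[pos - 1], []).append(rec.delta)
    return {
        base: {"median": float(np.median(vals)), "count": len(vals)}
        for base, vals in sorted(groups.items())
    }


def write_report_tsv(report: ComparisonReport, path: str | Path) -> None:
    Path(path).write_text(
        "subset\tn\tpearson_r\trmse\tmax_abs_diff\n"
        f"{report.subset_label}\t{report.n}\t{report.pearson_r:.6f}\t"
        f"{report.rmse:.6f}\t{report.max_abs_diff:.6f}\n"
    )
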