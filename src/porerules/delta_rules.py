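"""Current-shift (ΔC) tables, rule derivation and table imputation.

The central observation behind this package is that a base modification
shifts the expected nanopore current level of a k-mer in a way that is
largely determined by (i) where the modification sits inside the k-mer and
(ii) which bases flank its motif.  Those shifts can therefore be summarized
as a small ordered set of additive "ΔC rules":

* a **position rule** per modification position m — the median shift of all
  training k-mers modified at m;
* **pattern rules** (m, f, b) — an extra shift for k-mers modified at m that
  carry base b at flank position f, extracted iteratively as the median of
  the residuals of the matching k-mers, largest-magnitude pattern first,
  until no candidate median exceeds a stopping threshold r.

Applying the summed applicable rules to canonical levels imputes a complete
modified-k-mer table from partial training data (missing-imputed) or
denoises a fully trained one (fully-imputed).

Throughout, ΔC = modified level − canonical counterpart level, matching the
worked arithmetic of the rule walkthrough (e.g. canonical 11 plus rules
−4 − 2 + 1 gives an imputed modified level of 6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .model_io import (
    CANONICAL_BASES,
    KmerModel,
    ModelEntry,
    ModificationScheme,
    enumerate_modified_kmers,
    enumerate_multi_modified_kmers,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DeltaRecord",
    "DeltaTable",
    "Rule",
    "RuleSet",
    "DerivationConfig",
    "compute_delta",
    "derive_rules",
    "max_residual_median",
    "impute",
    "summarize_by_position",
    "write_rules",
    "read_rules",
    "detect_trained_kmers",
]


@dataclass(frozen=True)
class DeltaRecord:
    """ΔC observation for one trained modified k-mer."""

    kmer: str
    mod_position: int  # 1-based position of the modification code
    delta: float


@dataclass
class DeltaTable:
    """The training set: ΔC per trained single-modification k-mer."""

    scheme: ModificationScheme
    k: int
    records: list[DeltaRecord]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.kmer in seen:
                raise ValueError(f"duplicate k-mer in delta table: {rec.kmer}")
            seen.add(rec.kmer)

    def __len__(self) -> int:
        return len(self.records)

    def positions(self) -> list[int]:
        return sorted({rec.mod_position for rec in self.records})


@dataclass
class Rule:
    """One additive ΔC rule.

    ``kind == "position"`` rules carry the median shift for every k-mer
    modified at ``mod_position``; ``kind == "pattern"`` rules add ``shift``
    when the k-mer also has ``pattern_base`` at ``pattern_position``.
    ``order`` is the rank at which the rule was established.
    """

    mod_position: int
    kind: Literal["position", "pattern"]
    shift: float
    pattern_position: int | None = None
    pattern_base: str | None = None
    order: int = 0

    def __post_init__(self) -> None:
        if self.kind == "pattern":
            if self.pattern_position is None or self.pattern_base not in CANONICAL_BASES:
                raise ValueError("pattern rules need pattern_position and an ACGT pattern_base")
        elif self.kind == "position":
            if self.pattern_position is not None or self.pattern_base is not None:
                raise ValueError("position rules carry no pattern fields")
        else:
            raise ValueError(f"unknown rule kind {self.kind!r}")

    def matches(self, kmer: str, mod_position: int) -> bool:
        """Does this rule apply to a k-mer modified at ``mod_position``?

        Matching is against the k-mer as written, so a position holding a
        modification code never matches a canonical pattern base.
        """
        if mod_position != self.mod_position:
            return False
        if self.kind == "position":
            return True
        return kmer[self.pattern_position - 1] == self.pattern_base

    def pattern_string(self, k: int, scheme: ModificationScheme) -> str:
        """Render as an N-padded pattern, e.g. ``NNTMGN``."""
        chars = ["N"] * k
        start = self.mod_position - scheme.mod_offset
        for i, base in enumerate(scheme.motif):
            pos = start + i
            if 1 <= pos <= k:
                chars[pos - 1] = scheme.mod_code if i == scheme.mod_offset else base
        if self.kind == "pattern":
            chars[self.pattern_position - 1] = self.pattern_base
        return "".join(chars)


@dataclass
class RuleSet:
    """Ordered ΔC rules: per modification position one position rule
    followed by that position's pattern rules."""

    scheme: ModificationScheme
    k: int
    rules: list[Rule] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rules)

    def position_rule(self, mod_position: int) -> Rule | None:
        for rule in self.rules:
            if rule.kind == "position" and rule.mod_position == mod_position:
                return rule
        return None

    def pattern_rules(self, mod_position: int | None = None) -> list[Rule]:
        return [
            r
            for r in self.rules
            if r.kind == "pattern"
            and (mod_position is None or r.mod_position == mod_position)
        ]

    def shift_for(self, kmer: str, mod_position: int) -> float:
        """Summed shift of all rules applicable to ``kmer`` modified at
        ``mod_position``."""
        return sum(r.shift for r in self.rules if r.matches(kmer, mod_position))


@dataclass
class DerivationConfig:
    """Tunables of the rule-extraction loop.

    ``r`` is the stopping threshold in model units (default 0.01 — suited
    to pA-scale tables; rescale it with the table).  ``min_group_size``
    discards candidate patterns backed by fewer training k-mers.
    """

    r: float = 0.01
    max_iterations_per_position: int = 1000
    min_group_size: int = 1

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("stopping threshold r must be positive")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")


def _classify_kmer(kmer: str, scheme: ModificationScheme, k: int) -> int | None:
    """Return the 1-based modification position for a single-modification,
    complete-motif k-mer in the right motif context, else None."""
    count = kmer.count(scheme.mod_code)
    if count != 1:
        return None
    p = kmer.index(scheme.mod_code)  # 0-based
    start = p - scheme.mod_offset
    if start < 0 or start + len(scheme.motif) > k:
        return None
    if scheme.canonicalize(kmer)[start : start + len(scheme.motif)] != scheme.motif:
        return None
    return p + 1


def compute_delta(
    canonical: KmerModel,
    modified: KmerModel,
    scheme: ModificationScheme,
    trained: Iterable[str],
) -> DeltaTable:
    """ΔC = modified level − canonical counterpart level, per trained k-mer.

    Only single-modification k-mers whose motif lies completely inside the
    window contribute; multi-modification, incomplete-motif or wrong-context
    k-mers in ``trained`` are skipped with a warning.  A trained k-mer
    absent from the modified table raises ``KeyError``.
    """
    records: list[DeltaRecord] = []
    for kmer in sorted(set(trained)):
        if kmer not in modified.entries:
            raise KeyError(f"trained k-mer {kmer!r} absent from the modified table")
        m = _classify_kmer(kmer, scheme, modified.k)
        if m is None:
            logger.warning(
                "skipping trained k-mer %s: not a single-modification complete-motif k-mer",
                kmer,
            )
            continue
        counterpart = scheme.canonicalize(kmer)
        if counterpart not in canonical.entries:
            raise KeyError(f"canonical counterpart {counterpart!r} of {kmer!r} missing")
        records.append(
            DeltaRecord(kmer, m, modified.level(kmer) - canonical.level(counterpart))
        )
    return DeltaTable(scheme=scheme, k=modified.k, records=records)


def _candidate_positions(scheme: ModificationScheme, mod_position: int, k: int) -> list[int]:
    """Flank positions eligible for pattern rules: everything outside the
    motif footprint (inside it the base is constant, so its median residual
    is zero by construction)."""
    footprint = set(scheme.footprint(mod_position, k))
    return [f for f in range(1, k + 1) if f not in footprint]


def derive_rules(delta: DeltaTable, config: DerivationConfig | None = None) -> RuleSet:
    """Derive an ordered ΔC rule set by iterative median-residual extraction.

    For each modification position m present in the training set:

    1. Establish the position rule: the median ΔC of the group; subtract it
       to form residuals.
    2. Repeatedly find the flank pattern (f, b) — f outside the motif
       footprint, b in ACGT, at least ``min_group_size`` matching k-mers —
       whose matching residuals have the largest-magnitude median (ties:
       smallest f, then alphabetical b).  While that magnitude exceeds the
       stopping threshold r, record it as a pattern rule and subtract the
       median from the matching k-mers' residuals only.

    At termination every candidate pattern's median residual magnitude is
    at most r (re-checkable with :func:`max_residual_median`).
    """
    if not delta.records:
        raise ValueError("cannot derive rules from an empty delta table")
    config = config or DerivationConfig()
    rules: list[Rule] = []
    order = 0
    for m in delta.positions():
        group = [rec for rec in delta.records if rec.mod_position == m]
        residuals = np.array([rec.delta for rec in group], dtype=float)
        shift = float(np.median(residuals))
        rules.append(Rule(mod_position=m, kind="position", shift=shift, order=order))
        order += 1
        residuals -= shift
        # Pre-index members by (flank position, base).
        members: dict[tuple[int, str], np.ndarray] = {}
        for f in _candidate_positions(delta.scheme, m, delta.k):
            for b in CANONICAL_BASES:
                idx = np.array(
                    [i for i, rec in enumerate(group) if rec.kmer[f - 1] == b], dtype=int
                )
                if len(idx) >= config.min_group_size:
                    members[(f, b)] = idx
        for iteration in range(config.max_iterations_per_position + 1):
            best: tuple[int, str] | None = None
            best_med = 0.0
            for (f, b), idx in members.items():  # dict order: f ascending, b alphabetical
                med = float(np.median(residuals[idx]))
                if best is None or abs(med) > abs(best_med):
                    best, best_med = (f, b), med
            if best is None or abs(best_med) <= config.r:
                break
            if iteration == config.max_iterations_per_position:
                raise RuntimeError(
                    f"rule derivation did not converge at modification position {m}: "
                    f"pattern (f={best[0]}, b={best[1]}) still has median residual "
                    f"{best_med:.4g} after {config.max_iterations_per_position} iterations"
                )
            f, b = best
            rules.append(
                Rule(
                    mod_position=m,
                    kind="pattern",
                    shift=best_med,
                    pattern_position=f,
                    pattern_base=b,
                    order=order,
                )
            )
            order += 1
            residuals[members[(f, b)]] -= best_med
    return RuleSet(scheme=delta.scheme, k=delta.k, rules=rules)


def max_residual_median(
    delta: DeltaTable, rules: RuleSet, config: DerivationConfig | None = None
) -> float:
    """Largest-magnitude candidate-pattern median residual after applying a
    rule set to its training table — the termination certificate of
    :func:`derive_rules` (at most r for a freshly derived set)."""
    config = config or DerivationConfig()
    worst = 0.0
    for m in delta.positions():
        group = [rec for rec in delta.records if rec.mod_position == m]
        residuals = np.array(
            [rec.delta - rules.shift_for(rec.kmer, m) for rec in group], dtype=float
        )
        for f in _candidate_positions(delta.scheme, m, delta.k):
            for b in CANONICAL_BASES:
                vals = residuals[[rec.kmer[f - 1] == b for rec in group]]
                if len(vals) >= config.min_group_size:
                    worst = max(worst, abs(float(np.median(vals))))
    return worst


def summarize_by_position(delta: DeltaTable) -> dict[int, dict[str, float]]:
    """Median ΔC and group size per modification position — identical to
    the position-rule shifts :func:`derive_rules` would assign."""
    if not delta.records:
        raise ValueError("empty delta table")
    out: dict[int, dict[str, float]] = {}
    for m in delta.positions():
        vals = [rec.delta for rec in delta.records if rec.mod_position == m]
        out[m] = {"median": float(np.median(vals)), "count": len(vals)}
    return out


def impute(
    canonical: KmerModel,
    rules: RuleSet,
    mode: Literal["full", "missing"] = "full",
    trained_model: KmerModel | None = None,
    trained: Iterable[str] | None = None,
    include_multi: bool = False,
    include_incomplete: bool = False,
    inherit_trained_stdv: bool = False,
) -> KmerModel:
    """Build a modified-k-mer table from a canonical table and a rule set.

    Each modified k-mer's level is its canonical counterpart's level plus
    the position rule of its modification position plus every matching
    pattern rule.  ``mode="full"`` imputes (overwrites) every modified
    k-mer; ``mode="missing"`` copies trained entries verbatim from
    ``trained_model`` and imputes only the rest.  With ``include_multi``,
    k-mers carrying several modifications receive the summed per-position
    shifts.  Imputed entries keep the canonical counterpart's level_stdv
    (the +1 inflation is an untrained-placeholder convention, not a trained
    property); ``inherit_trained_stdv`` instead reuses the trained stdv
    where the k-mer exists in ``trained_model``.
    """
    if rules.k != canonical.k:
        raise ValueError(f"rule set k={rules.k} incompatible with canonical k={canonical.k}")
    if not canonical.is_complete_canonical():
        raise ValueError("canonical model must contain all ACGT k-mers")
    scheme = rules.scheme
    if mode == "missing":
        if trained_model is None or trained is None:
            raise ValueError("mode='missing' requires trained_model and trained")
        trained = set(trained)
    elif mode != "full":
        raise ValueError(f"unknown mode {mode!r}")

    k = canonical.k
    targets = sorted(enumerate_modified_kmers(k, scheme, include_incomplete))
    if include_multi:
        targets += sorted(enumerate_multi_modified_kmers(k, scheme))

    pos_shift = {r.mod_position: r.shift for r in rules.rules if r.kind == "position"}
    patterns: dict[int, list[Rule]] = {}
    for rule in rules.rules:
        if rule.kind == "pattern":
            patterns.setdefault(rule.mod_position, []).append(rule)

    out = canonical.copy()
    for kmer in targets:
        counterpart = scheme.canonicalize(kmer)
        base_entry = canonical.entries[counterpart]
        if mode == "missing" and kmer in trained:  # type: ignore[operator]
            if kmer not in trained_model.entries:  # type: ignore[union-attr]
                raise KeyError(f"trained k-mer {kmer!r} absent from trained_model")
            src = trained_model.entries[kmer]  # type: ignore[union-attr]
            out.entries[kmer] = ModelEntry(
                kmer, src.level_mean, src.level_stdv, src.sd_mean, src.sd_stdv, src.extra
            )
            continue
        total = 0.0
        mod_positions = [i + 1 for i, ch in enumerate(kmer) if ch == scheme.mod_code]
        for m in mod_positions:  # ascending; pure addition, order-free
            total += pos_shift.get(m, 0.0)
            for rule in patterns.get(m, ()):
                if kmer[rule.pattern_position - 1] == rule.pattern_base:
                    total += rule.shift
        stdv = base_entry.level_stdv
        if (
            inherit_trained_stdv
            and trained_model is not None
            and kmer in trained_model.entries
        ):
            stdv = trained_model.entries[kmer].level_stdv
        out.entries[kmer] = ModelEntry(
            kmer,
            base_entry.level_mean + total,
            stdv,
            base_entry.sd_mean,
            base_entry.sd_stdv,
            base_entry.extra,
        )
    out.alphabet = tuple(out.alphabet) + (scheme.mod_code,)
    return out


def detect_trained_kmers(
    modified: KmerModel,
    canonical: KmerModel,
    scheme: ModificationScheme,
    stdv_increment: float = 1.0,
    atol: float = 1e-9,
) -> set[str]:
    """Heuristically recover the trained inventory from an alphabet-expanded
    model: entries whose level_stdv still equals the canonical counterpart's
    stdv + ``stdv_increment`` are untrained placeholders; the rest were
    touched by training.  Logged, since this is a convention, not a fact."""
    trained: set[str] = set()
    for kmer in modified.modified_kmers():
        counterpart = scheme.canonicalize(kmer)
        if counterpart not in canonical.entries:
            continue
        placeholder = canonical.entries[counterpart].level_stdv + stdv_increment
        if abs(modified.entries[kmer].level_stdv - placeholder) > atol:
            trained.add(kmer)
    logger.info(
        "auto-detected %d trained k-mers (stdv differs from the canonical+%g placeholder)",
        len(trained),
        stdv_increment,
    )
    return trained


# ---------------------------------------------------------------------------
# Rule serialization: TSV with N-padded pattern strings such as NNTMGN.

def write_rules(rules: RuleSet, path: str | Path) -> None:
    """Serialize a rule set as TSV (order, kind, pattern, shift).

    Shifts use ``repr`` formatting so read(write(rules)) round-trips
    bit-exactly.
    """
    path = Path(path)
    lines = [
        f"#k={rules.k}",
        f"#scheme={rules.scheme}",
        "order\tkind\tpattern\tshift",
    ]
    for rule in rules.rules:
        lines.append(
            f"{rule.order}\t{rule.kind}\t{rule.pattern_string(rules.k, rules.scheme)}\t"
            f"{rule.shift!r}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_rules(path: str | Path) -> RuleSet:
    """Parse a rule TSV written by :func:`write_rules`."""
    path = Path(path)
    k: int | None = None
    scheme: ModificationScheme | None = None
    rules: list[Rule] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#k="):
            k = int(line[3:])
            continue
        if line.startswith("#scheme="):
            scheme = ModificationScheme.from_string(line[8:])
            continue
        if line.startswith("#") or line.startswith("order\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
        if k is None or scheme is None:
            raise ValueError(f"{path}: missing #k= / #scheme= header lines")
        order, kind, pattern, shift_s = fields
        rules.append(_parse_pattern(pattern, kind, float(shift_s), int(order), scheme, k, f"{path}:{lineno}"))
    if k is None or scheme is None:
        raise ValueError(f"{path}: missing #k= / #scheme= header lines")
    return RuleSet(scheme=scheme, k=k, rules=rules)


def _parse_pattern(
    pattern: str,
    kind: str,
    shift: float,
    order: int,
    scheme: ModificationScheme,
    k: int,
    where: str,
) -> Rule:
    if len(pattern) != k or pattern.count(scheme.mod_code) != 1:
        raise ValueError(f"{where}: malformed pattern string {pattern!r}")
    m = pattern.index(scheme.mod_code) + 1
    footprint = set(scheme.footprint(m, k))
    flank = [
        (i + 1, ch)
        for i, ch in enumerate(pattern)
        if ch != "N" and (i + 1) not in footprint
    ]
    if kind == "position":
        if flank:
            raise ValueError(f"{where}: position rule carries flank bases: {pattern!r}")
        return Rule(mod_position=m, kind="position", shift=shift, order=order)
    if kind != "pattern" or len(flank) != 1:
        raise ValueError(f"{where}: malformed {kind!r} rule pattern {pattern!r}")
    (f, b) = flank[0]
    if b not in CANONICAL_BASES:
        raise ValueError(f"{where}: pattern base {b!r} not in ACGT")
    return Rule(
        mod_position=m, kind="pattern", shift=shift, pattern_position=f, pattern_base=b, order=order
    )
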