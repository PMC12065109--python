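"""Synthetic inputs: genomes, canonical tables, ground-truth rule sets and
noisy partially trained modified tables.

Everything the pipeline consumes can be generated here deterministically
from a seed, so rule derivation, site selection and imputation are testable
end-to-end without any sequencing data.  Level and spread ranges mimic
pA-scale R9 pore models (levels roughly 60–130 pA).

Ground-truth rule sets are "balanced" by default: pattern rules at the same
(modification position, flank position) slot come as opposite-sign pairs.
The additive rule decomposition of a ΔC table is not unique in general —
two same-sign shifts at one flank slot displace the position-group median,
and derivation then converges to a different but observationally equivalent
rule set.  Balanced pairs keep every group median centred, so the ground
truth is identifiable and shift-recovery checks are well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .delta_rules import Rule, RuleSet
from .model_io import (
    CANONICAL_BASES,
    KmerModel,
    ModelEntry,
    ModificationScheme,
    enumerate_modified_kmers,
    enumerate_multi_modified_kmers,
)
from .site_selection import Genome, select_training_sites

__all__ = [
    "SyntheticTruth",
    "gen_genome",
    "gen_canonical_model",
    "gen_ruleset",
    "forward_apply",
    "add_noise",
    "holdout",
    "make_truth",
]


def gen_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random sequence with P(G) = P(C) = gc_fraction / 2."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    bases = rng.choice(list("ACGT"), size=length, p=[at, gc, gc, at])
    return "".join(bases)


def _all_kmers(k: int) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [km + b for km in kmers for b in CANONICAL_BASES]
    return kmers


def gen_canonical_model(
    k: int,
    seed: int = 0,
    level_range: tuple[float, float] = (60.0, 130.0),
    stdv_range: tuple[float, float] = (1.5, 4.0),
) -> KmerModel:
    """Complete canonical table with uniform-random levels and spreads."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    kmers = _all_kmers(k)
    levels = rng.uniform(*level_range, size=len(kmers))
    stdvs = rng.uniform(*stdv_range, size=len(kmers))
    entries = [
        ModelEntry(km, float(lv), float(sd)) for km, lv, sd in zip(kmers, levels, stdvs)
    ]
    header = [f"#synthetic canonical {k}-mer model (seed={seed})", "kmer\tlevel_mean\tlevel_stdv"]
    return KmerModel.from_entries(entries, header=header)


def gen_ruleset(
    scheme: ModificationScheme,
    k: int,
    n_pattern_rules: int,
    shift_magnitude: tuple[float, float] = (0.5, 5.0),
    min_separation: float = 0.1,
    seed: int = 0,
    balanced: bool = True,
) -> RuleSet:
    """Random ground-truth rule set: one position rule per modification
    position plus ``n_pattern_rules`` pattern rules without (m, f, b)
    collisions, all shift magnitudes at least ``min_separation``.

    With ``balanced`` (default), pattern rules are laid out as opposite-sign
    pairs sharing a (position, flank) slot, which makes the set identifiable
    by median-residual derivation (see module docstring).  Unbalanced sets
    draw independent (m, f, b) combinations and shifts.
    """
    rng = np.random.default_rng(seed)
    lo = max(shift_magnitude[0], min_separation)
    hi = shift_magnitude[1]
    if lo > hi:
        raise ValueError("shift_magnitude range incompatible with min_separation")
    # 1-based modification positions with a complete in-window motif.
    positions = [
        p + 1
        for p in range(k)
        if p - scheme.mod_offset >= 0 and p - scheme.mod_offset + len(scheme.motif) <= k
    ]
    if not positions:
        raise ValueError(f"no complete-motif placement for motif {scheme.motif!r} at k={k}")
    flanks = {
        m: [f for f in range(1, k + 1) if f not in set(scheme.footprint(m, k))]
        for m in positions
    }
    rules: list[Rule] = []
    for m in positions:
        mag = float(rng.uniform(lo, hi))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        rules.append(Rule(mod_position=m, kind="position", shift=sign * mag))

    pattern_rules: list[Rule] = []
    if balanced:
        slots = [(m, f) for m in positions for f in flanks[m]]
        capacity = 2 * len(slots)
        if n_pattern_rules > capacity:
            raise ValueError(
                f"n_pattern_rules={n_pattern_rules} exceeds balanced capacity {capacity} "
                f"(2 per position/flank slot)"
            )
        rng.shuffle(slots)
        remaining = n_pattern_rules
        for m, f in slots:
            if remaining <= 0:
                break
            mag = float(rng.uniform(lo, hi))
            bases = list(rng.choice(list(CANONICAL_BASES), size=2, replace=False))
            if remaining >= 2:
                pattern_rules.append(
                    Rule(m, "pattern", mag, pattern_position=f, pattern_base=bases[0])
                )
                pattern_rules.append(
                    Rule(m, "pattern", -mag, pattern_position=f, pattern_base=bases[1])
                )
                remaining -= 2
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                pattern_rules.append(
                    Rule(m, "pattern", sign * mag, pattern_position=f, pattern_base=bases[0])
                )
                remaining -= 1
    else:
        combos = [(m, f, b) for m in positions for f in flanks[m] for b in CANONICAL_BASES]
        if n_pattern_rules > len(combos):
            raise ValueError(
                f"n_pattern_rules={n_pattern_rules} exceeds available combinations {len(combos)}"
            )
        picks = rng.choice(len(combos), size=n_pattern_rules, replace=False)
        for i in picks:
            m, f, b = combos[i]
            mag = float(rng.uniform(lo, hi))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            pattern_rules.append(
                Rule(m, "pattern", sign * mag, pattern_position=f, pattern_base=b)
            )

    # Assemble in canonical order: per position, the position rule first,
    # then its pattern rules by descending magnitude (establishment order).
    ordered: list[Rule] = []
    for m in positions:
        ordered.append(next(r for r in rules if r.mod_position == m))
        ordered.extend(
            sorted(
                (r for r in pattern_rules if r.mod_position == m),
                key=lambda r: (-abs(r.shift), r.pattern_position, r.pattern_base),
            )
        )
    for i, rule in enumerate(ordered):
        rule.order = i
    return RuleSet(scheme=scheme, k=k, rules=ordered)


def forward_apply(
    canonical: KmerModel,
    rules: RuleSet,
    scheme: ModificationScheme | None = None,
    include_multi: bool = False,
) -> KmerModel:
    """Direct per-k-mer summation of applicable rule shifts.

    Deliberately naive — a linear scan of the rule list per target k-mer —
    so it serves as an independent oracle for ``impute(mode="full")``.
    """
    scheme = scheme or rules.scheme
    k = canonical.k
    targets = sorted(enumerate_modified_kmers(k, scheme, include_incomplete=False))
    if include_multi:
        targets += sorted(enumerate_multi_modified_kmers(k, scheme))
    out = canonical.copy()
    for kmer in targets:
        counterpart = scheme.canonicalize(kmer)
        base = canonical.entries[counterpart]
        total = 0.0
        for m in (i + 1 for i, ch in enumerate(kmer) if ch == scheme.mod_code):
            for rule in rules.rules:
                if rule.matches(kmer, m):
                    total += rule.shift
        out.entries[kmer] = ModelEntry(
            kmer, base.level_mean + total, base.level_stdv, base.sd_mean, base.sd_stdv
        )
    out.alphabet = tuple(out.alphabet) + (scheme.mod_code,)
    return out


def add_noise(
    model: KmerModel, sd: float, seed: int = 0, only_modified: bool = True
) -> KmerModel:
    """Gaussian perturbation of level_mean (spreads untouched).

    By default only modified k-mers are perturbed, emulating training noise
    on top of a known canonical table.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    out = model.copy()
    if sd == 0:
        return out
    rng = np.random.default_rng(seed)
    canon = set(CANONICAL_BASES)
    for kmer in sorted(out.entries):
        if only_modified and set(kmer) <= canon:
            continue
        out.entries[kmer].level_mean += float(rng.normal(0.0, sd))
    return out


def holdout(
    model: KmerModel,
    scheme: ModificationScheme,
    fraction: float,
    mode: Literal["kmer", "site"] = "kmer",
    genome: Genome | None = None,
    seed: int = 0,
) -> set[str]:
    """Choose a trained subset of the model's modified k-mers.

    ``mode="kmer"`` samples complete-motif single-modification k-mers
    uniformly; ``mode="site"`` delegates to genomic training-site selection,
    mirroring how training contexts arise from real motif sites.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    universe = sorted(
        enumerate_modified_kmers(model.k, scheme, include_incomplete=False)
        & set(model.entries)
    )
    if mode == "kmer":
        rng = np.random.default_rng(seed)
        n = int(round(fraction * len(universe)))
        picks = rng.choice(len(universe), size=n, replace=False)
        return {universe[i] for i in picks}
    if mode == "site":
        if genome is None:
            raise ValueError("mode='site' requires a genome")
        sel = select_training_sites(genome, scheme, model.k, fraction, seed=seed)
        return sel.covered_kmers & set(model.entries)
    raise ValueError(f"unknown holdout mode {mode!r}")


@dataclass
class SyntheticTruth:
    """A complete simulated study: canonical table, ground-truth rules,
    clean and noisy modified tables, and the trained inventory."""

    scheme: ModificationScheme
    canonical: KmerModel
    rules: RuleSet
    modified_clean: KmerModel
    modified_noisy: KmerModel
    trained: set[str]
    noise_sd: float
    seed: int
    genome: str | None = None


def make_truth(
    scheme: ModificationScheme,
    k: int = 6,
    n_pattern_rules: int = 10,
    noise_sd: float = 0.2,
    train_fraction: float = 0.25,
    holdout_mode: Literal["kmer", "site"] = "kmer",
    genome_length: int = 50_000,
    gc_fraction: float = 0.5,
    seed: int = 0,
    balanced: bool = True,
) -> SyntheticTruth:
    """Build a full synthetic study from one seed.

    Independent child seeds for the model, rules, noise, genome and holdout
    are drawn from ``seed`` so that components are uncorrelated but the
    whole study is reproducible.
    """
    root = np.random.default_rng(seed)
    sub = [int(s) for s in root.integers(0, 2**31 - 1, size=5)]
    canonical = gen_canonical_model(k, seed=sub[0])
    rules = gen_ruleset(scheme, k, n_pattern_rules, seed=sub[1], balanced=balanced)
    modified_clean = forward_apply(canonical, rules)
    modified_noisy = add_noise(modified_clean, noise_sd, seed=sub[2])
    genome = None
    if holdout_mode == "site":
        genome = gen_genome(genome_length, gc_fraction, seed=sub[3])
        trained = holdout(
            modified_noisy, scheme, train_fraction, mode="site",
            genome={"chr": genome}, seed=sub[4],
        )
    else:
        trained = holdout(modified_noisy, scheme, train_fraction, mode="kmer", seed=sub[4])
    return SyntheticTruth(
        scheme=scheme,
        canonical=canonical,
        rules=rules,
        modified_clean=modified_clean,
        modified_noisy=modified_noisy,
        trained=trained,
        noise_sd=noise_sd,
        seed=seed,
        genome=genome,
    )
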