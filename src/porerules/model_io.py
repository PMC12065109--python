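"""Read, write, expand and enumerate k-mer pore-model tables.

A pore model maps each k-mer to the ionic current level (and spread) it is
expected to produce while occupying the sensing region of a nanopore.  The
on-disk dialect is the tab-separated format used by Nanopolish and f5c::

    #model_name  something.model
    #alphabet    nucleotide
    kmer    level_mean  level_stdv  sd_mean  sd_stdv
    AAAAAA  86.141046   1.676522    1.391028 0.305543
    ...

``'#'``-prefixed metadata lines and the column-header line are preserved
verbatim on round trips.  Modified bases are represented by extending the
alphabet with a single-character modification code (conventionally ``M``)
placed at the modified position of the k-mer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

CANONICAL_BASES = "ACGT"

__all__ = [
    "CANONICAL_BASES",
    "ModificationScheme",
    "ModelEntry",
    "KmerModel",
    "read_model",
    "write_model",
    "expand_alphabet",
    "enumerate_modified_kmers",
    "enumerate_multi_modified_kmers",
]


@dataclass(frozen=True)
class ModificationScheme:
    """A base-modification motif, e.g. CpG methylation = ``CG:0:M``.

    Parameters
    ----------
    motif:
        Sequence context of the modification over ACGT, e.g. ``"CG"`` for
        CpG or ``"GC"`` for GpC.
    mod_offset:
        0-based index into ``motif`` of the base that becomes modified.
    mod_code:
        Single character (outside ACGT) marking the modified base in k-mers.
    """

    motif: str
    mod_offset: int = 0
    mod_code: str = "M"

    def __post_init__(self) -> None:
        if not self.motif or any(b not in CANONICAL_BASES for b in self.motif):
            raise ValueError(f"motif must be a non-empty ACGT string, got {self.motif!r}")
        if not 0 <= self.mod_offset < len(self.motif):
            raise ValueError(f"mod_offset {self.mod_offset} outside motif {self.motif!r}")
        if len(self.mod_code) != 1 or self.mod_code in CANONICAL_BASES:
            raise ValueError(f"mod_code must be a single non-ACGT character, got {self.mod_code!r}")

    @property
    def canonical_base(self) -> str:
        """The unmodified base at the modified motif position."""
        return self.motif[self.mod_offset]

    def canonicalize(self, kmer: str) -> str:
        """Replace every modification code with its canonical base."""
        return kmer.replace(self.mod_code, self.canonical_base)

    def footprint(self, mod_position: int, k: int) -> tuple[int, ...]:
        """1-based k-mer positions occupied by the in-window part of the
        motif when the modified base sits at ``mod_position`` (1-based)."""
        start = mod_position - self.mod_offset  # 1-based motif start
        return tuple(p for p in range(start, start + len(self.motif)) if 1 <= p <= k)

    @classmethod
    def from_string(cls, spec: str) -> "ModificationScheme":
        """Parse the ``MOTIF:OFFSET:CODE`` mini-format, e.g. ``"CG:0:M"``."""
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError(f"scheme spec must be MOTIF:OFFSET:CODE, got {spec!r}")
        return cls(parts[0].upper(), int(parts[1]), parts[2])

    def __str__(self) -> str:
        return f"{self.motif}:{self.mod_offset}:{self.mod_code}"


@dataclass
class ModelEntry:
    """One pore-model row: a k-mer with its expected current statistics."""

    kmer: str
    level_mean: float
    level_stdv: float
    sd_mean: float | None = None
    sd_stdv: float | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.level_stdv <= 0:
            raise ValueError(f"level_stdv must be positive for {self.kmer}: {self.level_stdv}")


@dataclass
class KmerModel:
    """An in-memory pore-model table.

    ``entries`` maps each k-mer to its :class:`ModelEntry`; ``header`` holds
    the verbatim metadata lines (including the column-header line, if the
    source file had one).
    """

    k: int
    alphabet: tuple[str, ...]
    entries: dict[str, ModelEntry]
    header: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        allowed = set(self.alphabet)
        for kmer in self.entries:
            if len(kmer) != self.k:
                raise ValueError(f"k-mer {kmer!r} has length {len(kmer)}, expected k={self.k}")
            if not set(kmer) <= allowed:
                raise ValueError(f"k-mer {kmer!r} uses characters outside alphabet {self.alphabet}")

    @classmethod
    def from_entries(cls, entries: Iterable[ModelEntry], header: list[str] | None = None) -> "KmerModel":
        emap = {e.kmer: e for e in entries}
        if not emap:
            raise ValueError("cannot infer k from an empty entry list")
        k = len(next(iter(emap)))
        chars = set().union(*(set(km) for km in emap))
        alphabet = tuple(b for b in CANONICAL_BASES if b in chars) + tuple(
            sorted(chars - set(CANONICAL_BASES))
        )
        return cls(k=k, alphabet=alphabet, entries=emap, header=list(header or []))

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, kmer: str) -> ModelEntry:
        return self.entries[kmer]

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def level(self, kmer: str) -> float:
        return self.entries[kmer].level_mean

    def copy(self) -> "KmerModel":
        return KmerModel(
            k=self.k,
            alphabet=self.alphabet,
            entries={km: replace(e) for km, e in self.entries.items()},
            header=list(self.header),
        )

    def modified_kmers(self) -> list[str]:
        """K-mers containing at least one non-ACGT character, sorted."""
        canon = set(CANONICAL_BASES)
        return sorted(km for km in self.entries if not set(km) <= canon)

    def is_complete_canonical(self) -> bool:
        """True if all 4**k ACGT k-mers are present."""
        n = sum(1 for km in self.entries if set(km) <= set(CANONICAL_BASES))
        return n == 4 ** self.k


def read_model(path: str | Path) -> KmerModel:
    """Read a Nanopolish/f5c-dialect pore-model table.

    Header metadata (``#`` lines) and the column-header line are kept
    verbatim so that :func:`write_model` can reproduce them.  ``sd_mean`` /
    ``sd_stdv`` columns are optional; any further columns are carried along
    unparsed.
    """
    path = Path(path)
    header: list[str] = []
    entries: dict[str, ModelEntry] = {}
    k: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if entries:
                    raise ValueError(f"{path}:{lineno}: metadata line after data rows")
                header.append(line)
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected tab-separated kmer and level columns")
            # A non-numeric second column marks the column-header line.
            if not entries and not _is_number(fields[1]):
                header.append(line)
                continue
            kmer = fields[0]
            if k is None:
                k = len(kmer)
            elif len(kmer) != k:
                raise ValueError(
                    f"{path}:{lineno}: k-mer {kmer!r} has length {len(kmer)}, "
                    f"inconsistent with k={k} inferred from the first entry"
                )
            try:
                level_mean = float(fields[1])
                level_stdv = float(fields[2]) if len(fields) > 2 else 1.0
                sd_mean = float(fields[3]) if len(fields) > 3 else None
                sd_stdv = float(fields[4]) if len(fields) > 4 else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric level field: {exc}") from None
            if kmer in entries:
                raise ValueError(f"{path}:{lineno}: duplicate k-mer {kmer!r}")
            entries[kmer] = ModelEntry(
                kmer, level_mean, level_stdv, sd_mean, sd_stdv, extra=tuple(fields[5:])
            )
    if not entries:
        raise ValueError(f"{path}: no data rows found")
    model = KmerModel.from_entries(entries.values(), header=header)
    return model


def write_model(model: KmerModel, path: str | Path) -> None:
    """Write a pore-model table: verbatim header, then entries sorted
    lexicographically by k-mer with fixed 6-decimal formatting (byte-stable
    output for identical models)."""
    path = Path(path)
    lines: list[str] = list(model.header)
    if not model.header:
        cols = ["kmer", "level_mean", "level_stdv"]
        if any(e.sd_mean is not None for e in model.entries.values()):
            cols += ["sd_mean", "sd_stdv"]
        lines.append("\t".join(cols))
    for kmer in sorted(model.entries):
        e = model.entries[kmer]
        fields = [kmer, f"{e.level_mean:.6f}", f"{e.level_stdv:.6f}"]
        if e.sd_mean is not None:
            fields.append(f"{e.sd_mean:.6f}")
            fields.append(f"{e.sd_stdv:.6f}" if e.sd_stdv is not None else "0.000000")
        fields.extend(e.extra)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def enumerate_modified_kmers(
    k: int, scheme: ModificationScheme, include_incomplete: bool = False
) -> set[str]:
    """All k-mers over ACGT + mod_code carrying exactly one modification.

    By default the motif must lie completely inside the k-mer window; for a
    motif of length L this gives (k − L + 1)·4**(k − L) k-mers (e.g. 1280 for
    a CpG scheme at k = 6).  With ``include_incomplete`` the motif may run
    off the window edge as long as the modified base itself is inside (e.g.
    ``NNNNNM`` for CpG, raising the count to 2304 at k = 6).
    """
    if k < len(scheme.motif):
        raise ValueError(f"k={k} smaller than motif length {len(scheme.motif)}")
    out: set[str] = set()
    for p in range(k):  # 0-based position of the modified base
        start = p - scheme.mod_offset
        end = start + len(scheme.motif)
        complete = start >= 0 and end <= k
        if not complete and not include_incomplete:
            continue
        template: list[str | None] = [None] * k
        for i, base in enumerate(scheme.motif):
            pos = start + i
            if 0 <= pos < k:
                template[pos] = scheme.mod_code if i == scheme.mod_offset else base
        free = [i for i in range(k) if template[i] is None]
        for combo in itertools.product(CANONICAL_BASES, repeat=len(free)):
            kmer = list(template)  # type: ignore[arg-type]
            for pos, base in zip(free, combo):
                kmer[pos] = base
            out.add("".join(kmer))  # type: ignore[arg-type]
    return out


def enumerate_multi_modified_kmers(k: int, scheme: ModificationScheme) -> set[str]:
    """K-mers carrying two or more modifications, each inside a complete
    in-window motif (e.g. ``MGMGMG`` for CpG at k = 6).

    Motif placements that would assign conflicting characters to a position
    are mutually exclusive and never combined.
    """
    if k < len(scheme.motif):
        raise ValueError(f"k={k} smaller than motif length {len(scheme.motif)}")
    placements = []
    for p in range(k):
        start = p - scheme.mod_offset
        if start >= 0 and start + len(scheme.motif) <= k:
            placements.append(p)
    out: set[str] = set()
    for n_mods in range(2, len(placements) + 1):
        for subset in itertools.combinations(placements, n_mods):
            template: list[str | None] = [None] * k
            ok = True
            for p in subset:
                start = p - scheme.mod_offset
                for i, base in enumerate(scheme.motif):
                    ch = scheme.mod_code if i == scheme.mod_offset else base
                    pos = start + i
                    if template[pos] is None:
                        template[pos] = ch
                    elif template[pos] != ch:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            free = [i for i in range(k) if template[i] is None]
            for combo in itertools.product(CANONICAL_BASES, repeat=len(free)):
                kmer = list(template)
                for pos, base in zip(free, combo):
                    kmer[pos] = base
                out.add("".join(kmer))  # type: ignore[arg-type]
    return out


def expand_alphabet(
    canonical: KmerModel,
    scheme: ModificationScheme,
    stdv_increment: float = 1.0,
    include_incomplete: bool = False,
    include_multi: bool = False,
) -> KmerModel:
    """Extend a canonical table with untrained placeholder entries for
    modified k-mers.

    Each new entry copies ``level_mean`` from its canonical counterpart
    (modification code replaced by the canonical base) and inflates
    ``level_stdv`` by ``stdv_increment`` — the convention Nanopolish uses to
    mark alphabet-expanded, not-yet-trained rows (default increment 1.0).
    """
    if scheme.mod_code in canonical.alphabet:
        raise ValueError(f"mod_code {scheme.mod_code!r} already present in model alphabet")
    if not canonical.is_complete_canonical():
        raise ValueError(
            f"canonical model is incomplete: expected all {4 ** canonical.k} ACGT "
            f"{canonical.k}-mers"
        )
    k = canonical.k
    targets = set(enumerate_modified_kmers(k, scheme, include_incomplete))
    if include_multi:
        targets |= enumerate_multi_modified_kmers(k, scheme)
    out = canonical.copy()
    for kmer in sorted(targets):
        counterpart = scheme.canonicalize(kmer)
        if counterpart not in canonical.entries:
            raise ValueError(f"canonical counterpart {counterpart!r} of {kmer!r} missing")
        src = canonical.entries[counterpart]
        out.entries[kmer] = ModelEntry(
            kmer,
            src.level_mean,
            src.level_stdv + stdv_increment,
            src.sd_mean,
            src.sd_stdv,
            src.extra,
        )
    out.alphabet = tuple(out.alphabet) + (scheme.mod_code,)
    return out
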