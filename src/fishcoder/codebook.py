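"""Combinatorial barcode codebook over a (round, channel) pseudocolor space.

A gene's barcode is an unordered set of 4 pseudocolors from the
n_rounds x n_channels acquisition grid (default 22 x 2 = 44).  Pairwise
barcode intersections are capped at ``max_shared`` (default 2), which
makes every 3-subset of every barcode unique to one gene — the property
that lets a call missing one position (3 of 4 detected) still decode
unambiguously.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Pseudocolor:
    """One (hybridization round, fluorescence channel) imaging slot."""

    round: int
    channel: int
    n_channels: int

    @property
    def flat(self) -> int:
        return self.round * self.n_channels + self.channel


def build_pseudocolor_space(n_rounds: int, n_channels: int) -> list[Pseudocolor]:
    """All pseudocolors in row-major (round-major) order."""
    if n_rounds < 1 or n_channels < 1:
        raise ValueError("n_rounds and n_channels must be >= 1")
    return [
        Pseudocolor(r, c, n_channels)
        for r in range(n_rounds)
        for c in range(n_channels)
    ]


def flat_to_round_channel(flat: int, n_channels: int) -> tuple[int, int]:
    return divmod(flat, n_channels)


@dataclass(frozen=True)
class Barcode:
    gene_id: str
    pseudocolors: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.pseudocolors) != 4:
            raise ValueError(f"{self.gene_id}: barcode must have 4 distinct pseudocolors")


class CodebookCapacityError(RuntimeError):
    """Gene list exceeds the achievable barcode packing."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"requested {requested} barcodes but packing capacity reached at {achieved}"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass
class Codebook:
    n_rounds: int = 22
    n_channels: int = 2
    max_shared: int = 2
    barcodes: dict[str, Barcode] = field(default_factory=dict)

    @property
    def n_pseudocolors(self) -> int:
        return self.n_rounds * self.n_channels

    def genes(self) -> list[str]:
        return list(self.barcodes)

    def triple_lookup(self) -> dict[frozenset[int], str]:
        """Map every 3-subset of every barcode to its gene.

        Well defined whenever pairwise sharing <= 2 holds.
        """
        table: dict[frozenset[int], str] = {}
        for gid, bc in self.barcodes.items():
            for trip in itertools.combinations(sorted(bc.pseudocolors), 3):
                key = frozenset(trip)
                if key in table and table[key] != gid:
                    raise ValueError(
                        f"3-subset {sorted(trip)} shared by {table[key]} and {gid}"
                    )
                table[key] = gid
        return table


def _pack_greedy(
    n_slots: int, rng: np.random.Generator, limit: int | None, max_shared: int = 2
) -> list[frozenset[int]]:
    """Greedy randomized 4-subset packing with pairwise sharing <= max_shared.

    Accepting a 4-set only if none of its (max_shared+1)-subsets was
    used before enforces pairwise intersection <= max_shared between
    accepted sets (default: unique 3-subsets, sharing <= 2).
    """
    m = max_shared + 1
    combos = list(itertools.combinations(range(n_slots), 4))
    rng.shuffle(combos)
    used: set[tuple[int, ...]] = set()
    packed: list[frozenset[int]] = []
    for quad in combos:
        subs = list(itertools.combinations(quad, m))
        if any(s in used for s in subs):
            continue
        used.update(subs)
        packed.append(frozenset(quad))
        if limit is not None and len(packed) >= limit:
            break
    return packed


def assign_barcodes(
    gene_ids: list[str],
    space: list[Pseudocolor] | None = None,
    max_shared: int = 2,
    rng_seed: int = 0,
    n_rounds: int = 22,
    n_channels: int = 2,
) -> Codebook:
    """Assign each gene a barcode by greedy randomized packing.

    Deterministic given ``rng_seed``; raises CodebookCapacityError with
    the achieved capacity if the gene list cannot be packed.
    """
    if space is not None:
        n_slots = len(space)
        n_channels = space[0].n_channels
        n_rounds = n_slots // n_channels
    else:
        n_slots = n_rounds * n_channels
    if n_slots < 4:
        raise ValueError("pseudocolor space must contain at least 4 slots")
    if not 1 <= max_shared <= 3:
        raise ValueError("max_shared must be in [1, 3]")
    rng = np.random.default_rng(rng_seed)
    packed = _pack_greedy(n_slots, rng, limit=len(gene_ids), max_shared=max_shared)
    if len(packed) < len(gene_ids):
        raise CodebookCapacityError(len(gene_ids), len(packed))
    cb = Codebook(n_rounds, n_channels, max_shared)
    for gid, quad in zip(gene_ids, packed):
        cb.barcodes[gid] = Barcode(gid, quad)
    return cb


def packing_capacity(
    n_rounds: int = 22, n_channels: int = 2, rng_seed: int = 0
) -> int:
    """Run the greedy packer to exhaustion and report how many barcodes fit."""
    rng = np.random.default_rng(rng_seed)
    return len(_pack_greedy(n_rounds * n_channels, rng, limit=None))


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


def validate_codebook(cb: Codebook) -> ValidationReport:
    """Check barcode weight, pairwise sharing, and 3-subset uniqueness."""
    report = ValidationReport()
    n = cb.n_pseudocolors
    for gid, bc in cb.barcodes.items():
        if len(bc.pseudocolors) != 4:
            report.violations.append(f"{gid}: weight {len(bc.pseudocolors)} != 4")
        if any(p < 0 or p >= n for p in bc.pseudocolors):
            report.violations.append(f"{gid}: pseudocolor out of range")
    items = sorted(cb.barcodes.items())
    for (ga, a), (gb, b) in itertools.combinations(items, 2):
        shared = len(a.pseudocolors & b.pseudocolors)
        if shared > cb.max_shared:
            report.violations.append(
                f"{ga}/{gb}: share {shared} pseudocolors (> {cb.max_shared})"
            )
    return report


# ----------------------------------------------------------------------
# serialization: CSV with '#'-prefixed metadata header lines

def write_codebook_csv(cb: Codebook, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_rounds={cb.n_rounds}\n")
        fh.write(f"# n_channels={cb.n_channels}\n")
        fh.write(f"# max_shared={cb.max_shared}\n")
        fh.write("gene_id,r1,c1,r2,c2,r3,c3,r4,c4\n")
        for gid, bc in cb.barcodes.items():
            parts = []
            for flat in sorted(bc.pseudocolors):
                r, c = flat_to_round_channel(flat, cb.n_channels)
                parts += [str(r), str(c)]
            fh.write(gid + "," + ",".join(parts) + "\n")


def read_codebook_csv(path) -> Codebook:
    meta: dict[str, int] = {}
    rows: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = int(val)
                continue
            rows.append((lineno, line))
    header, data = rows[0], rows[1:]
    if not header[1].startswith("gene_id"):
        raise ValueError(f"{path}:{header[0]}: expected header starting with gene_id")
    cb = Codebook(
        meta.get("n_rounds", 22), meta.get("n_channels", 2), meta.get("max_shared", 2)
    )
    for lineno, line in data:
        parts = line.split(",")
        if len(parts) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 fields, got {len(parts)}")
        gid = parts[0]
        try:
            vals = [int(p) for p in parts[1:]]
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-integer pseudocolor field") from e
        flats = frozenset(
            r * cb.n_channels + c for r, c in zip(vals[0::2], vals[1::2])
        )
        cb.barcodes[gid] = Barcode(gid, flats)
    return cb
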