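"""Combinatorial barcode decoding from a spot table.

Each detected spot seeds a neighbor search: for every gene whose barcode
contains the seed's pseudocolor, the nearest spot within the linking
radius (default 2.5 px, inclusive) is collected in each of the gene's
other three pseudocolors.  A candidate is viable when seed plus
companions cover at least ``min_positions`` (default 3) distinct barcode
positions; when several genes are viable for one seed the most complete
match wins, minimum total seed-to-companion distance breaks ties among
equally complete candidates, and exact ties drop the seed as ambiguous.
Seeding is repeated from every barcode position, same-gene candidates
sharing a spot are reconciled by iterative extraction, and cross-gene
claims on a spot are resolved globally so that no spot ends up in two
calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .codebook import Codebook
from .spotcall import SpotTable


@dataclass
class DecodeConfig:
    radius: float = 2.5  # inclusive linking radius, px
    min_positions: int = 3
    seed_all_positions: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not 1 <= self.min_positions <= 4:
            raise ValueError("min_positions must be in [1, 4]")


@dataclass
class DecodedCall:
    gene_id: str
    x: float
    y: float
    n_positions: int
    total_distance: float
    spot_refs: tuple[int, ...]


@dataclass
class _Candidate:
    gene_id: str
    spots: frozenset[int]
    total_distance: float
    seed: int


def _nearest_within(
    tree: cKDTree, ids: np.ndarray, xy: np.ndarray, point: np.ndarray, radius: float
) -> tuple[int, float] | None:
    """Nearest neighbor within an inclusive radius; ties by lowest id."""
    idx = tree.query_ball_point(point, radius + 1e-9)
    if not idx:
        return None
    d = np.linalg.norm(xy[idx] - point, axis=1)
    keep = d <= radius
    if not keep.any():
        return None
    idx = np.asarray(idx)[keep]
    d = d[keep]
    best = np.lexsort((ids[idx], d))[0]
    return int(ids[idx][best]), float(d[best])


def _generate_candidates(
    df: pd.DataFrame, cb: Codebook, cfg: DecodeConfig
) -> list[_Candidate]:
    """Per-seed candidate generation (steps 1-4 of the procedure)."""
    barcode_of = {g: tuple(sorted(cb.barcodes[g].pseudocolors)) for g in sorted(cb.barcodes)}
    genes_by_pc: dict[int, list[str]] = {}
    for g, bc in barcode_of.items():
        for pc in bc:
            genes_by_pc.setdefault(pc, []).append(g)

    trees: dict[int, tuple[cKDTree, np.ndarray, np.ndarray]] = {}
    for pc, sub in df.groupby("pseudocolor"):
        xy = sub[["x", "y"]].to_numpy()
        trees[int(pc)] = (cKDTree(xy), sub.index.to_numpy(), xy)

    pos = df[["x", "y"]].to_numpy()
    pcs = df["pseudocolor"].to_numpy()
    candidates: list[_Candidate] = []
    for i in range(len(df)):
        seed_pc = int(pcs[i])
        viable: list[_Candidate] = []
        for g in genes_by_pc.get(seed_pc, []):
            bc = barcode_of[g]
            if not cfg.seed_all_positions and seed_pc != bc[0]:
                continue
            members = {i}
            total = 0.0
            for pc in bc:
                if pc == seed_pc or pc not in trees:
                    continue
                tree, ids, xy = trees[pc]
                hit = _nearest_within(tree, ids, xy, pos[i], cfg.radius)
                if hit is not None:
                    members.add(hit[0])
                    total += hit[1]
            if len(members) >= cfg.min_positions:
                viable.append(_Candidate(g, frozenset(members), total, i))
        if not viable:
            continue
        # prefer complete (4-position) matches; minimum total distance
        # breaks ties among equally complete candidates
        best = min(viable, key=lambda c: (-len(c.spots), c.total_distance))
        ties = [
            c for c in viable
            if len(c.spots) == len(best.spots)
            and c.total_distance == best.total_distance
        ]
        if len(ties) > 1 and len({c.gene_id for c in ties}) > 1:
            continue  # ambiguous seed: multiple barcodes at identical distance
        candidates.append(best)
    return candidates


def _merge_and_resolve(
    candidates: list[_Candidate],
    df: pd.DataFrame,
    cb: Codebook,
    cfg: DecodeConfig,
) -> list[DecodedCall]:
    """Steps 5-7: same-gene merging and global cross-gene resolution."""
    pcs = df["pseudocolor"].to_dict()
    intens = df["intensity"].to_dict() if "intensity" in df else {}

    # deduplicate identical (gene, spot set), keeping the best distance
    uniq: dict[tuple[str, frozenset[int]], _Candidate] = {}
    for c in candidates:
        key = (c.gene_id, c.spots)
        if key not in uniq or c.total_distance < uniq[key].total_distance:
            uniq[key] = c

    # union-find over same-gene candidates sharing >= 1 spot
    per_gene: dict[str, list[_Candidate]] = {}
    for c in uniq.values():
        per_gene.setdefault(c.gene_id, []).append(c)

    calls: list[dict] = []
    for g in sorted(per_gene):
        cands = sorted(per_gene[g], key=lambda c: (-len(c.spots), c.total_distance, c.seed))
        parent = list(range(len(cands)))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        spot_owner: dict[int, int] = {}
        for k, c in enumerate(cands):
            for s in c.spots:
                if s in spot_owner:
                    ra, rb = find(k), find(spot_owner[s])
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
                else:
                    spot_owner[s] = k
        groups: dict[int, list[_Candidate]] = {}
        for k, c in enumerate(cands):
            groups.setdefault(find(k), []).append(c)
        for root in sorted(groups):
            # iterative extraction: the best candidate claims its spots,
            # the rest of the group is re-evaluated on what remains, so
            # two same-gene transcripts that overlap still yield two
            # calls instead of collapsing into one
            members = groups[root]  # already in (completeness, distance, seed) order
            used: set[int] = set()
            for c in members:
                remaining = c.spots - used
                if len(remaining) < cfg.min_positions:
                    continue
                if len({pcs[s] for s in remaining}) < cfg.min_positions:
                    continue
                calls.append(
                    {
                        "gene_id": g,
                        "spots": set(remaining),
                        "total_distance": c.total_distance,
                    }
                )
                used |= remaining

    # global cross-gene conflict resolution: a spot claimed by calls of
    # different genes goes to the smaller-total_distance call
    changed = True
    while changed:
        changed = False
        claims: dict[int, list[int]] = {}
        for ci, call in enumerate(calls):
            for s in call["spots"]:
                claims.setdefault(s, []).append(ci)
        for s, owners in sorted(claims.items()):
            if len(owners) < 2:
                continue
            owners = sorted(
                owners,
                key=lambda ci: (
                    -len(calls[ci]["spots"]),
                    calls[ci]["total_distance"],
                    calls[ci]["gene_id"],
                ),
            )
            for ci in owners[1:]:
                calls[ci]["spots"].discard(s)
                changed = True
        calls = [c for c in calls if len(c["spots"]) >= cfg.min_positions]

    out: list[DecodedCall] = []
    for call in calls:
        refs = tuple(sorted(call["spots"]))
        w = np.array([intens.get(s, 1.0) for s in refs], dtype=float)
        if w.sum() <= 0:
            w = np.ones(len(refs))
        xs = np.array([df.at[s, "x"] for s in refs])
        ys = np.array([df.at[s, "y"] for s in refs])
        out.append(
            DecodedCall(
                call["gene_id"],
                float(np.average(xs, weights=w)),
                float(np.average(ys, weights=w)),
                len(refs),
                call["total_distance"],
                refs,
            )
        )
    out.sort(key=lambda c: (c.gene_id, c.y, c.x))
    return out


def decode_spots(
    spots: SpotTable | pd.DataFrame, cb: Codebook, cfg: DecodeConfig | None = None
) -> list[DecodedCall]:
    """Decode a registered spot table into validated gene calls.

    The result is invariant to input row order (spots are canonicalized
    internally) and to global translation of all coordinates.  Every
    final call covers >= ``cfg.min_positions`` distinct barcode
    positions and no spot belongs to two calls.
    """
    cfg = cfg or DecodeConfig()
    df = spots.spots if isinstance(spots, SpotTable) else spots
    if len(df) == 0:
        return []
    df = df.copy()
    if "intensity" not in df:
        df["intensity"] = 1.0
    if "spot_id" not in df:
        df["spot_id"] = np.arange(len(df))
    # canonical internal order decouples the result from caller ordering
    df = df.sort_values(
        ["pseudocolor", "y", "x", "intensity"], kind="mergesort"
    ).reset_index(drop=True)
    candidates = _generate_candidates(df, cb, cfg)
    calls = _merge_and_resolve(candidates, df, cb, cfg)
    # map internal indices back to caller spot ids
    sid = df["spot_id"].to_dict()
    return [
        DecodedCall(
            c.gene_id, c.x, c.y, c.n_positions, c.total_distance,
            tuple(sorted(sid[s] for s in c.spot_refs)),
        )
        for c in calls
    ]


def calls_to_frame(calls: list[DecodedCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "x": c.x,
                "y": c.y,
                "n_positions": c.n_positions,
                "total_distance": c.total_distance,
                "spot_refs": ";".join(map(str, c.spot_refs)),
            }
            for c in calls
        ],
        columns=["gene_id", "x", "y", "n_positions", "total_distance", "spot_refs"],
    )


# ----------------------------------------------------------------------
# evaluation against simulated truth

@dataclass
class DecodeMetrics:
    recall: float
    precision: float
    rmse: float
    per_gene: pd.DataFrame
    gene_correlation: float
    n_true: int
    n_called: int
    n_matched: int

    def to_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "rmse": self.rmse,
            "gene_correlation": self.gene_correlation,
            "n_true": self.n_true,
            "n_called": self.n_called,
            "n_matched": self.n_matched,
        }


def evaluate_decoding(
    calls: list[DecodedCall], truth, match_radius: float = 2.0
) -> DecodeMetrics:
    """Greedy nearest matching of calls to true transcripts per gene.

    ``truth`` is a GroundTruth or a transcripts DataFrame with columns
    gene_id, x, y.
    """
    tdf = truth.transcripts if hasattr(truth, "transcripts") else truth
    genes = sorted(set(tdf["gene_id"]) | {c.gene_id for c in calls})
    n_matched = 0
    sq = []
    rows = []
    for g in genes:
        t = tdf[tdf["gene_id"] == g][["x", "y"]].to_numpy()
        c = np.array([[cc.x, cc.y] for cc in calls if cc.gene_id == g])
        m = 0
        if len(t) and len(c):
            d = np.linalg.norm(t[:, None, :] - c[None, :, :], axis=2)
            pairs = np.argwhere(d <= match_radius)
            order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
            used_t: set[int] = set()
            used_c: set[int] = set()
            for ti, ci in pairs[order]:
                if ti in used_t or ci in used_c:
                    continue
                used_t.add(int(ti))
                used_c.add(int(ci))
                sq.append(d[ti, ci] ** 2)
                m += 1
        n_matched += m
        rows.append({"gene_id": g, "n_true": len(t), "n_called": len(c), "n_matched": m})
    per_gene = pd.DataFrame(rows)
    n_true = int(per_gene["n_true"].sum())
    n_called = int(per_gene["n_called"].sum())
    recall = n_matched / n_true if n_true else 1.0
    precision = n_matched / n_called if n_called else 1.0
    rmse = float(np.sqrt(np.mean(sq))) if sq else 0.0
    if len(per_gene) > 1 and per_gene["n_true"].std() > 0 and per_gene["n_called"].std() > 0:
        corr = float(np.corrcoef(per_gene["n_true"], per_gene["n_called"])[0, 1])
    else:
        corr = 1.0
    return DecodeMetrics(recall, precision, rmse, per_gene, corr, n_true, n_called, n_matched)
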