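"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's data structures and spatial
indices: plain nested loops over lists, so they stand as a second,
independent realization of the same decoding and screening rules.
"""

from __future__ import annotations

import math


def shares_kmer_bruteforce(a: str, b: str, k: int) -> bool:
    """True iff a and b share any exact substring of length k (one strand)."""
    subs = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in subs for i in range(len(b) - k + 1))


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq))


def site_survives_bruteforce(target: str, background: list[str], k: int) -> bool:
    """Off-target screen decision by all-substring scanning on both strands."""
    for bg in background:
        if shares_kmer_bruteforce(target, bg, k):
            return False
        if shares_kmer_bruteforce(target, revcomp(bg), k):
            return False
    return True


def oracle_decode(rows, barcodes, radius=2.5, min_positions=3):
    """Brute-force decoder over a list of spot dicts.

    ``rows``: dicts with spot_id, pseudocolor, x, y, intensity, already
    in canonical (pseudocolor, y, x, intensity) order with spot_id equal
    to position.  ``barcodes``: gene_id -> set of 4 pseudocolors.
    Returns a sorted list of (gene_id, spot_ref_tuple).
    """
    genes = sorted(barcodes)
    # step 1-4: per-seed candidates by exhaustive scan
    candidates = []
    for seed in rows:
        viable = []
        for g in genes:
            bc = sorted(barcodes[g])
            if seed["pseudocolor"] not in bc:
                continue
            members = {seed["spot_id"]}
            total = 0.0
            for pc in bc:
                if pc == seed["pseudocolor"]:
                    continue
                best = None
                for s in rows:
                    if s["pseudocolor"] != pc:
                        continue
                    d = math.sqrt(
                        (s["x"] - seed["x"]) ** 2 + (s["y"] - seed["y"]) ** 2
                    )
                    if d <= radius and (best is None or (d, s["spot_id"]) < best):
                        best = (d, s["spot_id"])
                if best is not None:
                    members.add(best[1])
                    total += best[0]
            if len(members) >= min_positions:
                viable.append((g, frozenset(members), total, seed["spot_id"]))
        if not viable:
            continue
        best = min(viable, key=lambda v: (-len(v[1]), v[2]))
        ties = [
            v for v in viable if len(v[1]) == len(best[1]) and v[2] == best[2]
        ]
        if len(ties) > 1 and len({v[0] for v in ties}) > 1:
            continue
        candidates.append(best)

    # dedupe: keep the earliest-seeded minimum-distance representative
    uniq = {}
    for g, spots, total, seed_id in candidates:
        key = (g, spots)
        if key not in uniq or total < uniq[key][0]:
            uniq[key] = (total, seed_id)
    cands = [(g, spots, t_s[0], t_s[1]) for (g, spots), t_s in uniq.items()]

    pc_of = {r["spot_id"]: r["pseudocolor"] for r in rows}
    # per-gene connected components over shared spots, then iterative
    # extraction in (completeness, distance) order
    calls = []
    for g in genes:
        mine = [c for c in cands if c[0] == g]
        if not mine:
            continue
        # build components by repeated merging
        comps: list[list] = []
        for c in mine:
            touching = [comp for comp in comps if any(c[1] & m[1] for m in comp)]
            merged = [c]
            for comp in touching:
                merged.extend(comp)
                comps.remove(comp)
            comps.append(merged)
        # deterministic component order: by best (completeness, distance, seed)
        def comp_key(comp):
            return min((-len(m[1]), m[2], m[3]) for m in comp)

        for comp in sorted(comps, key=comp_key):
            comp = sorted(comp, key=lambda m: (-len(m[1]), m[2], m[3]))
            used = set()
            for _, spots, total, _seed in comp:
                remaining = spots - used
                if len(remaining) < min_positions:
                    continue
                if len({pc_of[s] for s in remaining}) < min_positions:
                    continue
                calls.append({"gene_id": g, "spots": set(remaining), "total": total})
                used |= remaining

    # global conflict resolution
    changed = True
    while changed:
        changed = False
        claims = {}
        for ci, call in enumerate(calls):
            for s in call["spots"]:
                claims.setdefault(s, []).append(ci)
        for s in sorted(claims):
            owners = claims[s]
            if len(owners) < 2:
                continue
            owners = sorted(
                owners,
                key=lambda ci: (
                    -len(calls[ci]["spots"]),
                    calls[ci]["total"],
                    calls[ci]["gene_id"],
                ),
            )
            for ci in owners[1:]:
                calls[ci]["spots"].discard(s)
                changed = True
        calls = [c for c in calls if len(c["spots"]) >= min_positions]

    return sorted((c["gene_id"], tuple(sorted(c["spots"]))) for c in calls)
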