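"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain double loops over explicit
definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

BASES = set("ACGT")


def oracle_p_distance(a: str, b: str) -> tuple[float | None, int]:
    """Proportion of differing sites among columns where both rows have an
    unambiguous base. Returns (None, n) when nothing is comparable."""
    assert len(a) == len(b)
    n = 0
    mism = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in BASES and y in BASES:
            n += 1
            if x != y:
                mism += 1
    if n == 0:
        return None, 0
    return mism / n, n


def oracle_distance_matrix(
    rows: dict[str, str], min_overlap: int
) -> dict[tuple[str, str], float | None]:
    """All-pairs p-distance; None encodes 'missing' (overlap below floor)."""
    out: dict[tuple[str, str], float | None] = {}
    ids = list(rows)
    for i, a in enumerate(ids):
        out[(a, a)] = 0.0
        for b in ids[i + 1 :]:
            d, n = oracle_p_distance(rows[a], rows[b])
            val = d if (d is not None and n >= min_overlap) else None
            out[(a, b)] = val
            out[(b, a)] = val
    return out


def oracle_thresh_id(
    acc: str,
    dist: dict[tuple[str, str], float | None],
    labels: dict[str, str],
    threshold: float,
) -> tuple[str, set[str]]:
    """Outcome of one sequence: (outcome, neighbour accessions)."""
    neighbors = {
        other
        for other in labels
        if other != acc
        and dist[(acc, other)] is not None
        and dist[(acc, other)] <= threshold
    }
    if not neighbors:
        return "no_id", neighbors
    species = {labels[n] for n in neighbors}
    if species == {labels[acc]}:
        return "correct", neighbors
    if labels[acc] in species:
        return "ambiguous", neighbors
    return "incorrect", neighbors


def oracle_species_resolution(
    dist: dict[tuple[str, str], float | None],
    labels: dict[str, str],
    threshold: float,
    universe: set[str],
) -> dict[str, tuple[str, set[str]]]:
    """Category and partner set per species, by exhaustive graph walk."""
    present = set(labels.values())
    edges: set[frozenset[str]] = set()
    for a in labels:
        for b in labels:
            if (
                a != b
                and labels[a] != labels[b]
                and dist[(a, b)] is not None
                and dist[(a, b)] <= threshold
            ):
                edges.add(frozenset((labels[a], labels[b])))

    def component(sp: str) -> set[str]:
        comp = {sp}
        frontier = [sp]
        while frontier:
            cur = frontier.pop()
            for e in edges:
                if cur in e:
                    (other,) = e - {cur} or {cur}
                    if other not in comp:
                        comp.add(other)
                        frontier.append(other)
        return comp

    out: dict[str, tuple[str, set[str]]] = {}
    for sp in universe:
        if sp not in present:
            out[sp] = ("no_reference", set())
            continue
        comp = component(sp)
        if len(comp) == 1:
            out[sp] = ("species", set())
        elif len(comp) == 2:
            out[sp] = ("sister_species", comp - {sp})
        else:
            out[sp] = ("multiple_species", comp - {sp})
    return out


def oracle_global_alignment_score(
    a: str,
    b: str,
    match: float,
    mismatch: float,
    open_gap: float,
    extend_gap: float,
) -> float:
    """Optimal global alignment score with affine gaps and free end gaps,
    by explicit Gotoh dynamic programming."""
    import math

    n, m = len(a), len(b)
    NEG = -math.inf
    # M: a[i] aligned to b[j]; X: gap in b (a consumed); Y: gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free leading end gap in b
    for j in range(1, m + 1):
        Y[0][j] = 0.0  # free leading end gap in a
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if j == m:  # trailing gaps in b are free
                X[i][j] = max(M[i - 1][j], X[i - 1][j], Y[i - 1][j])
            else:
                X[i][j] = max(M[i - 1][j] + open_gap, X[i - 1][j] + extend_gap)
            if i == n:  # trailing gaps in a are free
                Y[i][j] = max(M[i][j - 1], X[i][j - 1], Y[i][j - 1])
            else:
                Y[i][j] = max(M[i][j - 1] + open_gap, Y[i][j - 1] + extend_gap)
    return max(M[n][m], X[n][m], Y[n][m])
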