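"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a pipeline quantity by the most direct method
available — explicit dynamic programming, exhaustive enumeration, plain
interval arithmetic — sharing no code with the package paths it checks.
"""

from __future__ import annotations

NEG = float("-inf")


# ---------------------------------------------------------------------------
# affine-gap global alignment (Gotoh) with traceback
# ---------------------------------------------------------------------------


def gotoh_score(ref: str, query: str, match: float = 2.0, mismatch: float = -4.0,
                gap_open: float = -6.0, gap_extend: float = -1.0) -> float:
    """Optimal global affine-gap score; a gap of length L costs
    gap_open + (L-1)*gap_extend."""
    n, m = len(ref), len(query)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (ref consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (query consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == query[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def gotoh_indels(ref: str, query: str, match: float = 2.0,
                 mismatch: float = -4.0, gap_open: float = -6.0,
                 gap_extend: float = -1.0) -> list[tuple[int, int, str]]:
    """One optimal alignment's indels as left-aligned (start, span, alt).

    Adjacent deletion/insertion runs merge into one replacement; pure
    indels are shifted to their leftmost equivalent position.
    """
    n, m = len(ref), len(query)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == query[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    # traceback
    i, j = n, m
    state = max(("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m]),
                key=lambda t: t[1])[0]
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = match if ref[i - 1] == query[j - 1] else mismatch
            prev = M[i][j] - s
            ops.append("M")
            for cand in ("M", "X", "Y"):
                val = {"M": M, "X": X, "Y": Y}[cand][i - 1][j - 1]
                if abs(val - prev) < 1e-9:
                    state = cand
                    break
            i, j = i - 1, j - 1
        elif state == "X":
            ops.append("D")
            val = X[i][j]
            if i > 1 or j > 0:
                if abs(M[i - 1][j] + gap_open - val) < 1e-9:
                    state = "M"
                elif abs(X[i - 1][j] + gap_extend - val) < 1e-9:
                    state = "X"
                else:
                    state = "Y"
            i -= 1
        else:
            ops.append("I")
            val = Y[i][j]
            if j > 1 or i > 0:
                if abs(M[i][j - 1] + gap_open - val) < 1e-9:
                    state = "M"
                elif abs(Y[i][j - 1] + gap_extend - val) < 1e-9:
                    state = "Y"
                else:
                    state = "X"
            j -= 1
    ops.reverse()
    # collect gap runs (D/I mixed runs merge into one event)
    events: list[tuple[int, int, str]] = []
    ri = qi = 0
    k = 0
    while k < len(ops):
        if ops[k] == "M":
            ri += 1
            qi += 1
            k += 1
            continue
        span = 0
        alt = ""
        start = ri
        while k < len(ops) and ops[k] != "M":
            if ops[k] == "D":
                span += 1
                ri += 1
            else:
                alt += query[qi]
                qi += 1
            k += 1
        events.append(_left_shift(ref, start, span, alt))
    return events


def _left_shift(ref: str, start: int, span: int, alt: str) -> tuple[int, int, str]:
    if span > 0 and not alt:
        while start > 0 and ref[start - 1] == ref[start + span - 1]:
            start -= 1
    elif span == 0 and alt:
        while start > 0 and ref[start - 1] == alt[-1]:
            alt = ref[start - 1] + alt[:-1]
            start -= 1
    return (start, span, alt)


# ---------------------------------------------------------------------------
# read-pair merging by exhaustive offset search
# ---------------------------------------------------------------------------


def brute_merge(fwd: str, fwd_q: str, rev: str, rev_q: str,
                min_overlap: int = 10,
                max_mismatch_frac: float = 0.1) -> str | None:
    comp = str.maketrans("ACGTN", "TGCAN")
    r = rev.translate(comp)[::-1]
    rq = rev_q[::-1]
    best = None  # (matches, overlap)
    for o in range(min_overlap, min(len(fwd), len(r)) + 1):
        matches = sum(a == b for a, b in zip(fwd[-o:], r[:o]))
        if (o - matches) / o <= max_mismatch_frac:
            if best is None or (matches, o) >= best:
                best = (matches, o)
    if best is None:
        return None
    _, o = best
    mid = []
    for fb, rb, fq, rq_ in zip(fwd[-o:], r[:o], fwd_q[-o:], rq[:o]):
        mid.append(fb if fb == rb or fq >= rq_ else rb)
    return fwd[: len(fwd) - o] + "".join(mid) + r[o:]


# ---------------------------------------------------------------------------
# exhaustive Hamming guide scan
# ---------------------------------------------------------------------------


def brute_scan(genome: dict[str, str], protospacer: str,
               max_mm: int) -> set[tuple[str, int, str, int]]:
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = protospacer.translate(comp)[::-1]
    k = len(protospacer)
    hits = set()
    for chrom, seq in genome.items():
        seq = seq.upper()
        for pos in range(len(seq) - k + 1):
            window = seq[pos:pos + k]
            for strand, pat in (("+", protospacer), ("-", rc)):
                mm = sum(a != b for a, b in zip(window, pat))
                if mm <= max_mm:
                    hits.add((chrom, pos, strand, mm))
    return hits


# ---------------------------------------------------------------------------
# deletion filter cascade by direct interval arithmetic
# ---------------------------------------------------------------------------


def brute_filter(events, control_events, polymorphic, repeats, coverage,
                 min_size=4, max_size=100_000, pad=5, identity=0.80,
                 max_cov=250):
    """Re-derive retained events and the first-failing-filter tally."""
    tally = {"size": 0, "control_breakpoint": 0, "polymorphic": 0,
             "repeat": 0, "control_coverage": 0}
    retained = []

    def cov_at(chrom, pos):
        arr = coverage.get(chrom)
        if arr is None or len(arr) == 0:
            return 0
        return int(arr[min(max(pos, 0), len(arr) - 1)])

    for ev in events:
        size = ev.end - ev.start
        if size < min_size or size > max_size:
            tally["size"] += 1
            continue
        near_control = any(
            ev.chrom == c.chrom and abs(bp - cbp) <= pad
            for c in control_events for cbp in (c.start, c.end)
            for bp in (ev.start, ev.end))
        if near_control:
            tally["control_breakpoint"] += 1
            continue
        poly_hit = False
        for chrom, ps, pe in polymorphic:
            if chrom != ev.chrom:
                continue
            inter = min(ev.end, pe) - max(ev.start, ps)
            if inter > 0 and min(inter / size, inter / (pe - ps)) > identity:
                poly_hit = True
        if poly_hit:
            tally["polymorphic"] += 1
            continue
        rep_hit = any(
            chrom == ev.chrom and bp - pad < re and bp + pad + 1 > rs
            for chrom, rs, re in repeats for bp in (ev.start, ev.end))
        if rep_hit:
            tally["repeat"] += 1
            continue
        if any(cov_at(ev.chrom, bp) > max_cov for bp in (ev.start, ev.end)):
            tally["control_coverage"] += 1
            continue
        retained.append(ev)
    tally["retained"] = len(retained)
    return retained, tally


# ---------------------------------------------------------------------------
# transitive interval clustering via union-find
# ---------------------------------------------------------------------------


def union_find_clusters(intervals: list[tuple[str, int, int]],
                        pad: int) -> list[set[int]]:
    """Groups of interval indices whose padded intervals chain together."""
    parent = list(range(len(intervals)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, (ci, si, ei) in enumerate(intervals):
        for j, (cj, sj, ej) in enumerate(intervals):
            if i < j and ci == cj and si - pad < ej + pad and sj - pad < ei + pad:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(len(intervals)):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())
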