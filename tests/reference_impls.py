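"""Independent naive reference implementations used as test oracles.

Everything here is deliberately written as plain Python loops, straight from
the stated contracts, and shares no code with the package implementations it
checks.
"""

from itertools import combinations

MISSING = -1


def naive_detect_roh(calls, chrom, pos, params):
    """Window/flag/segment ROH scan as five literal steps.

    Returns a list of (chrom, start, end, n_snps, n_het) tuples.
    """
    out = []
    for c in dict.fromkeys(list(chrom)):
        idx = [k for k in range(len(chrom)) if chrom[k] == c]
        g = [int(calls[k]) for k in idx]
        p = [int(pos[k]) for k in idx]
        n = len(g)
        w = params.window_snps
        if n < w:
            continue
        # (1) score every contiguous window
        windows = list(range(n - w + 1))
        wpass = []
        for s in windows:
            het = sum(1 for k in range(s, s + w) if g[k] == 1)
            mis = sum(1 for k in range(s, s + w) if g[k] == MISSING)
            wpass.append(
                het <= params.window_het_max and mis <= params.window_missing_max
            )
        # (2) flag SNPs by hit rate over containing windows
        flags = []
        for i in range(n):
            containing = [s for s in windows if s <= i <= s + w - 1]
            frac = sum(wpass[s] for s in containing) / len(containing)
            flags.append(frac >= params.hit_threshold)
        # (3) maximal flagged runs split at big gaps
        runs = []
        start = None
        for i in range(n + 1):
            inside = i < n and flags[i]
            if inside and start is not None and p[i] - p[i - 1] > params.gap_kb * 1000:
                runs.append((start, i - 1))
                start = i
            elif inside and start is None:
                start = i
            elif not inside and start is not None:
                runs.append((start, i - 1))
                start = None
        # (4) trim to homozygous non-missing ends; (5) acceptance rules
        for a, b in runs:
            while a <= b and g[a] not in (0, 2):
                a += 1
            while b >= a and g[b] not in (0, 2):
                b -= 1
            if a > b:
                continue
            n_snps = b - a + 1
            length = p[b] - p[a] + 1
            n_het = sum(1 for k in range(a, b + 1) if g[k] == 1)
            if n_snps < params.min_snps:
                continue
            if length < params.min_length_kb * 1000:
                continue
            if length / n_snps > params.density_kb_per_snp * 1000:
                continue
            if params.segment_het_max is not None and n_het > params.segment_het_max:
                continue
            out.append((c, p[a], p[b], n_snps, n_het))
    return out


def naive_genotype_filter(calls, gq, depth, min_gq, max_missing_frac, min_depth):
    """Two-rule genotype filter applied literally; returns surviving site indices."""
    n_samples = len(calls)
    n_sites = len(calls[0])
    masked = [row[:] for row in calls]
    for i in range(n_samples):
        for j in range(n_sites):
            if masked[i][j] == MISSING:
                continue
            if gq[i][j] < min_gq or depth[i][j] <= min_depth - 1:
                masked[i][j] = MISSING
    kept = []
    for j in range(n_sites):
        miss = sum(1 for i in range(n_samples) if masked[i][j] == MISSING)
        if miss / n_samples <= max_missing_frac:
            kept.append(j)
    return kept


def naive_hard_filter(info_rows):
    """Per-site hard-filter verdicts; ``info_rows`` maps field name -> value or None."""
    rules = [
        ("QD", "<", 2.0), ("QUAL", "<", 30.0), ("SOR", ">", 3.0),
        ("FS", ">", 60.0), ("MQ", "<", 40.0), ("MQRankSum", "<", -12.5),
        ("ReadPosRankSum", "<", -8.0),
    ]
    kept = []
    for j, row in enumerate(info_rows):
        ok = True
        for key, op, thresh in rules:
            val = row.get(key)
            if val is None:
                continue
            if (op == "<" and val < thresh) or (op == ">" and val > thresh):
                ok = False
        if ok:
            kept.append(j)
    return kept


def naive_r2(a, b):
    """Pearson r² over pairwise-complete samples; None when undefined."""
    pairs = [(x, y) for x, y in zip(a, b) if x != MISSING and y != MISSING]
    if len(pairs) < 2:
        return None
    xs = [x for x, _ in pairs]
    ys = [y for _, y in pairs]
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    if vx == 0 or vy == 0:
        return None
    cov = sum((x - mx) * (y - my) for x, y in pairs)
    return (cov * cov) / (vx * vy)


def min_vertex_cover_size(nodes, edges):
    """Exact minimum vertex cover by subset enumeration (use only for <= ~12 nodes)."""
    nodes = list(nodes)
    if not edges:
        return 0
    for size in range(1, len(nodes) + 1):
        for cover in combinations(nodes, size):
            cset = set(cover)
            if all(u in cset or v in cset for u, v in edges):
                return size
    return len(nodes)
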