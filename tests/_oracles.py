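"""Independent brute-force reference implementations used only by the
test suite.  Deliberately literal: explicit Python loops over cells and
threat pixels, no convolution, no vectorized shortcuts, so they check
the production code paths rather than share them."""

from __future__ import annotations

import math

import numpy as np


def degradation_bruteforce(landcover, threats, specs, sens, accessibility=None):
    """Literal quadruple-loop evaluation of the weighted degradation sum:
    every valid cell x against every threat pixel y of every layer."""
    spec_by = {s.name: s for s in specs}
    total_w = sum(spec_by[name].weight for name in threats)
    nr, nc = landcover.shape
    cell = landcover.cell_size
    D = np.full((nr, nc), np.nan)
    threat_cells = {
        name: list(zip(*np.nonzero(layer.values == 1)))
        for name, layer in threats.items()
    }
    for r in range(nr):
        for c in range(nc):
            code = int(landcover.values[r, c])
            if code == landcover.nodata:
                continue
            jname = landcover.legend.name(code)
            beta = 1.0 if accessibility is None else accessibility.values[r, c]
            acc = 0.0
            for name in threats:
                spec = spec_by[name]
                s_jr = sens.sensitivity(jname, name)
                dmax = spec.max_dist_m
                for (yr, yc) in threat_cells[name]:
                    d = math.hypot(r - yr, c - yc) * cell
                    if d > dmax:
                        i = 0.0
                    elif spec.decay == "linear":
                        i = 1.0 - d / dmax
                    else:
                        i = math.exp(-2.99 * d / dmax)
                    acc += (spec.weight / total_w) * i * beta * s_jr
            D[r, c] = acc
    return D


def _neighbors(r, c, nr, nc, connectivity):
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for dr, dc in steps:
        rr, cc = r + dr, c + dc
        if 0 <= rr < nr and 0 <= cc < nc:
            yield rr, cc


def count_patches_bruteforce(landcover, connectivity=8):
    """Flood-fill count of same-class connected components."""
    vals = landcover.values
    nr, nc = vals.shape
    seen = np.zeros((nr, nc), dtype=bool)
    n = 0
    for r in range(nr):
        for c in range(nc):
            if seen[r, c] or vals[r, c] == landcover.nodata:
                continue
            n += 1
            stack = [(r, c)]
            seen[r, c] = True
            code = vals[r, c]
            while stack:
                rr, cc = stack.pop()
                for nr_, nc_ in _neighbors(rr, cc, nr, nc, connectivity):
                    if not seen[nr_, nc_] and vals[nr_, nc_] == code:
                        seen[nr_, nc_] = True
                        stack.append((nr_, nc_))
    return n


def shdi_bruteforce(landcover):
    vals = landcover.values
    counts = {}
    for v in vals.ravel():
        if v != landcover.nodata:
            counts[int(v)] = counts.get(int(v), 0) + 1
    total = sum(counts.values())
    return -sum(
        (n / total) * math.log(n / total) for n in counts.values() if n > 0
    )


def adjacency_bruteforce(landcover):
    """Exhaustive 4-neighbor pair enumeration, each pair counted once in
    each direction; pairs touching nodata excluded."""
    vals = landcover.values
    nr, nc = vals.shape
    codes = sorted(
        {int(v) for v in vals.ravel() if v != landcover.nodata}
    )
    idx = {c: i for i, c in enumerate(codes)}
    g = np.zeros((len(codes), len(codes)), dtype=np.int64)
    for r in range(nr):
        for c in range(nc):
            a = vals[r, c]
            if a == landcover.nodata:
                continue
            for rr, cc in ((r + 1, c), (r, c + 1)):
                if rr < nr and cc < nc:
                    b = vals[rr, cc]
                    if b == landcover.nodata:
                        continue
                    g[idx[int(a)], idx[int(b)]] += 1
                    g[idx[int(b)], idx[int(a)]] += 1
    return g, codes


def contag_bruteforce(landcover):
    """CONTAG from the brute-force adjacency table and composition."""
    g, codes = adjacency_bruteforce(landcover)
    if len(codes) < 2:
        return float("nan")
    vals = landcover.values
    total = sum(1 for v in vals.ravel() if v != landcover.nodata)
    acc = 0.0
    for i, ci in enumerate(codes):
        p_i = (vals == ci).sum() / total
        row = g[i].sum()
        for k in range(len(codes)):
            if row > 0 and g[i, k] > 0:
                p_ik = p_i * g[i, k] / row
                acc += p_ik * math.log(p_ik)
    m = len(codes)
    return 100.0 * (1.0 + acc / (2.0 * math.log(m)))
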