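"""Independent brute-force reference implementations used only by tests.

Every function here is written for clarity, not speed, and deliberately
avoids the code paths of the package (plain Python loops wherever feasible)
so it can serve as an oracle.
"""

import math

import numpy as np


def brute_acf_first_nonpositive(x, cap):
    """First lag k >= 1 with sample autocorrelation <= 0, else cap."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = float(sum(v * v for v in xc))
    for k in range(1, cap + 1):
        num = float(sum(xc[i] * xc[i + k] for i in range(len(x) - k)))
        if num / denom <= 0.0:
            return k
    return cap


def brute_recurrence_matrix(traj, eps):
    traj = np.atleast_2d(traj)
    if traj.shape[0] == 1:
        traj = traj.T
    n = len(traj)
    R = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            d = math.sqrt(sum((traj[i, c] - traj[j, c]) ** 2
                              for c in range(traj.shape[1])))
            R[i, j] = d < eps
    return R


def brute_diag_hist(R, exclude_loi=True):
    n = len(R)
    hist = {}
    for off in range(-(n - 1), n):
        if exclude_loi and off == 0:
            continue
        cells = [(i, i + off) for i in range(n)
                 if 0 <= i + off < n and 0 <= i < n]
        run = 0
        for (i, j) in cells:
            if R[i, j]:
                run += 1
            else:
                if run:
                    hist[run] = hist.get(run, 0) + 1
                run = 0
        if run:
            hist[run] = hist.get(run, 0) + 1
    return hist


def brute_vert_hist(R):
    n = len(R)
    hist = {}
    for j in range(n):
        run = 0
        for i in range(n):
            if R[i, j]:
                run += 1
            else:
                if run:
                    hist[run] = hist.get(run, 0) + 1
                run = 0
        if run:
            hist[run] = hist.get(run, 0) + 1
    return hist


def brute_rqa(R, lmin=2, vmin=2):
    """All RQA scalars from a binary matrix, by direct enumeration."""
    n = len(R)
    n_rec = int(R.sum()) - n
    rec = n_rec / (n * n - n)
    dh = brute_diag_hist(R, exclude_loi=True)
    vh = brute_vert_hist(R)

    d_pts = sum(l * c for l, c in dh.items() if l >= lmin)
    det = d_pts / n_rec if n_rec > 0 else 0.0
    ratio = det / rec if rec > 0 else float("nan")
    d_lines = sum(c for l, c in dh.items() if l >= lmin)
    lmax = max([l for l in dh if l >= lmin and dh[l] > 0], default=0)
    lmean = d_pts / d_lines if d_lines else 0.0
    div = 1.0 / lmax if lmax else float("inf")
    entr = 0.0
    if d_lines:
        for l, c in dh.items():
            if l >= lmin and c:
                p = c / d_lines
                entr -= p * math.log(p)

    v_pts = sum(l * c for l, c in vh.items() if l >= vmin)
    lam = v_pts / int(R.sum()) if R.sum() else 0.0
    v_lines = sum(c for l, c in vh.items() if l >= vmin)
    vmax = max([l for l in vh if l >= vmin and vh[l] > 0], default=0)
    vmean = v_pts / v_lines if v_lines else 0.0
    return dict(REC=rec, DET=det, RATIO=ratio, Lmax=float(lmax), Lmean=lmean,
                DIV=div, ENTR=entr, LAM=lam, Vmax=float(vmax), Vmean=vmean)


def brute_morans_i(values, valid, weight_fn):
    """Direct double-sum Moran's I over valid sites of a 2-D grid.

    ``weight_fn((i1,j1),(i2,j2))`` returns the weight between two sites.
    """
    sites = [(i, j) for i in range(values.shape[0])
             for j in range(values.shape[1]) if valid[i, j]]
    n = len(sites)
    xbar = sum(values[s] for s in sites) / n
    denom = sum((values[s] - xbar) ** 2 for s in sites)
    if denom == 0:
        return float("nan")
    s0 = 0.0
    num = 0.0
    for a in sites:
        for b in sites:
            w = weight_fn(a, b)
            s0 += w
            num += w * (values[a] - xbar) * (values[b] - xbar)
    return n / s0 * num / denom


def moore_weight(a, b):
    if a == b:
        return 0.0
    return 1.0 if max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1 else 0.0


def naive_apen(x, m, r):
    """Pincus approximate entropy by direct template counting."""
    x = np.asarray(x, dtype=float)
    n = len(x)

    def phi(mm):
        cnt = n - mm + 1
        total = 0.0
        for i in range(cnt):
            c = 0
            for j in range(cnt):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
            total += math.log(c / cnt)
        return total / cnt

    return phi(m) - phi(m + 1)


def naive_sampen_counts(x, m, r):
    """(A, B): numbers of m+1 and m template matches, self excluded."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    cnt = n - m

    def matches(mm):
        c = 0
        for i in range(cnt):
            for j in range(cnt):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    return matches(m + 1), matches(m)


def naive_sampen(x, m, r):
    a, b = naive_sampen_counts(x, m, r)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)
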