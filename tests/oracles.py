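"""Independent oracles used by the test suite.

Each function recomputes a quantity by a different route than the package:
exhaustive grid search instead of quasi-Newton optimisation, dense sampling
instead of the measurement pipeline, textbook ANOVA sums of squares instead
of the packaged estimator.
"""

import numpy as np


def grid_max_loglike(y, is_mz, step=0.001, refine=True):
    """Exhaustive search of the twin-ACE likelihood over standardized shares.

    The mean (GLS, scale-free) and total variance (average Mahalanobis form)
    are concentrated in closed form at every grid node, so the search space
    is the (A, C) simplex at the given resolution.  Intercept-only mean.
    """
    y = np.asarray(y, float)
    n = len(y)
    stats = {}
    for g, mask in (("mz", np.asarray(is_mz)), ("dz", ~np.asarray(is_mz))):
        yy = y[mask]
        stats[g] = dict(n=len(yy), s1=yy.sum(), s2=(yy ** 2).sum(),
                        sx=(yy[:, 0] * yy[:, 1]).sum())

    def evaluate(TA, TC):
        r_mz = np.minimum(TA + TC, 1 - 1e-10)
        r_dz = np.minimum(0.5 * TA + TC, 1 - 1e-10)
        w_mz = 1.0 / (1.0 + r_mz)
        w_dz = 1.0 / (1.0 + r_dz)
        num = w_mz * stats["mz"]["s1"] + w_dz * stats["dz"]["s1"]
        den = 2.0 * (w_mz * stats["mz"]["n"] + w_dz * stats["dz"]["n"])
        mu = num / den
        q = np.zeros_like(mu)
        logdet = np.zeros_like(mu)
        for g, r in (("mz", r_mz), ("dz", r_dz)):
            st = stats[g]
            s2c = st["s2"] - 2 * mu * st["s1"] + 2 * st["n"] * mu ** 2
            sxc = st["sx"] - mu * st["s1"] + st["n"] * mu ** 2
            q += (s2c - 2 * r * sxc) / (1 - r ** 2)
            logdet += st["n"] * np.log(1 - r ** 2)
        sigma2 = q / (2 * n)
        return -n * np.log(2 * np.pi) - n * np.log(sigma2) - 0.5 * logdet - n

    ta = np.arange(0.0, 1.0 + 1e-12, step)
    TA, TC = np.meshgrid(ta, ta, indexing="ij")
    keep = TA + TC <= 1.0
    TA, TC = TA[keep], TC[keep]
    ll = evaluate(TA, TC)
    i = int(np.argmax(ll))
    best = (float(ll[i]), float(TA[i]), float(TC[i]))
    if refine:
        # local refinement around the coarse argmax, still pure search
        a0, c0 = best[1], best[2]
        fine = step / 50.0
        ga = np.clip(a0 + np.arange(-60, 61) * fine, 0.0, 1.0)
        gc = np.clip(c0 + np.arange(-60, 61) * fine, 0.0, 1.0)
        FA, FC = np.meshgrid(ga, gc, indexing="ij")
        keep = FA + FC <= 1.0
        FA, FC = FA[keep], FC[keep]
        llf = evaluate(FA, FC)
        j = int(np.argmax(llf))
        if llf[j] > best[0]:
            best = (float(llf[j]), float(FA[j]), float(FC[j]))
    return best


def anova_icc(pairs):
    """Textbook one-way ANOVA intraclass correlation for groups of two."""
    pairs = np.asarray(pairs, float)
    n = pairs.shape[0]
    pair_means = pairs.mean(axis=1)
    grand = pairs.mean()
    msb = 2.0 * np.sum((pair_means - grand) ** 2) / (n - 1)
    msw = np.sum((pairs - pair_means[:, None]) ** 2) / n
    return (msb - msw) / (msb + msw)


def dense_bend_oracle(curve_fn, t0, t1, n=100_000):
    """Arc-length-weighted median |x| of a parametric curve via dense sampling."""
    t = np.linspace(t0, t1, n)
    pts = curve_fn(t)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    xm = np.abs(0.5 * (pts[:-1, 0] + pts[1:, 0]))
    order = np.argsort(xm)
    cw = np.cumsum(seg[order])
    return float(xm[order][np.searchsorted(cw, 0.5 * seg.sum())])


def spline_frenet_oracle(points):
    """Curvature/torsion from analytic derivatives of a cubic-spline fit."""
    from scipy.interpolate import CubicSpline

    pts = np.asarray(points, float)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    cs = CubicSpline(s, pts)
    ss = np.linspace(s[2], s[-3], 400)
    d1, d2, d3 = cs(ss, 1), cs(ss, 2), cs(ss, 3)
    cross = np.cross(d1, d2)
    ncross = np.linalg.norm(cross, axis=1)
    kappa = ncross / np.linalg.norm(d1, axis=1) ** 3
    tau = np.einsum("ij,ij->i", cross, d3) / ncross ** 2
    return kappa, tau
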