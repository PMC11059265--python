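"""Independent brute-force oracles used to check package implementations.

Everything here is written from the verbal measure definitions with plain
Python loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats as spstats


def bf_time_measures(ml, v, ap, gml, gv, gap, fs):
    """Brute-force recomputation of all 43 time-domain measures."""
    ml, v, ap = (np.asarray(x, float) for x in (ml, v, ap))
    gml, gv, gap = (np.asarray(x, float) for x in (gml, gv, gap))
    n = len(ml)
    T = n / fs
    dt = 1.0 / fs
    svm = np.array([math.sqrt(ml[i] ** 2 + v[i] ** 2 + ap[i] ** 2) for i in range(n)])
    gsvm = np.array(
        [math.sqrt(gml[i] ** 2 + gv[i] ** 2 + gap[i] ** 2) for i in range(n)]
    )
    out = {}

    def scalar_path(x):
        return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))

    axes = {"SVM": svm, "ML": ml, "V": v, "AP": ap}
    gyro = {"SVM": gsvm, "ML": gml, "V": gv, "AP": gap}
    for ax, x in axes.items():
        out[f"MDIST-{ax}"] = sum(abs(xi) for xi in x) / n
        tot = scalar_path(x)
        out[f"TOTEX-{ax}"] = tot
        out[f"NPL-{ax}"] = tot / n
        out[f"MVELO-{ax}"] = tot / T
        out[f"RMS-{ax}"] = math.sqrt(sum(xi**2 for xi in x) / n)
        g = gyro[ax]
        out[f"RMS-G-{ax}"] = math.sqrt(sum(gi**2 for gi in g) / n)

    mean_svm = sum(svm) / n
    out["AAMV"] = sum(abs(s - mean_svm) for s in svm) / n

    planes = {
        "AP-ML": (ap, ml),
        "ML-V": (ml, v),
        "AP-V": (ap, v),
    }
    out["R-SVM"] = max(svm) - min(svm)
    out["JERK-SVM"] = sum(
        ((svm[i + 1] - svm[i]) / dt) ** 2 for i in range(n - 1)
    ) * dt
    for pl, (a, b) in planes.items():
        ra = max(a) - min(a)
        rb = max(b) - min(b)
        out[f"R-{pl}"] = math.sqrt(ra**2 + rb**2)
        ja = sum(((a[i + 1] - a[i]) / dt) ** 2 for i in range(n - 1)) * dt
        jb = sum(((b[i + 1] - b[i]) / dt) ** 2 for i in range(n - 1)) * dt
        out[f"JERK-{pl}"] = ja + jb

    # areas on the AP-ML plane
    rd = [math.hypot(ml[i], ap[i]) for i in range(n)]
    mdist_p = sum(rd) / n
    sd_rd = math.sqrt(sum((r - mdist_p) ** 2 for r in rd) / (n - 1))
    out["AREA-CC"] = math.pi * (mdist_p + 1.645 * sd_rd) ** 2

    m_ml = sum(ml) / n
    m_ap = sum(ap) / n
    s_ml2 = sum((x - m_ml) ** 2 for x in ml) / (n - 1)
    s_ap2 = sum((x - m_ap) ** 2 for x in ap) / (n - 1)
    s_apml = sum((ap[i] - m_ap) * (ml[i] - m_ml) for i in range(n)) / (n - 1)
    det = s_ap2 * s_ml2 - s_apml**2
    if det <= 0:
        out["AREA-CE"] = 0.0
    else:
        out["AREA-CE"] = (
            2 * math.pi * spstats.f.ppf(0.95, 2, n - 2) * math.sqrt(det)
        )
    out["AREA-SW"] = sum(
        abs(ap[i + 1] * ml[i] - ap[i] * ml[i + 1]) for i in range(n - 1)
    ) / (2 * T)

    sma = sum(abs(ml[i]) + abs(v[i]) + abs(ap[i]) for i in range(n)) / n
    out["SMA"] = sma
    for ax in ("ML", "V", "AP"):
        saa = sum(axes[ax])
        out[f"SAA-{ax}"] = saa
        out[f"R-SAA-SMA-{ax}"] = saa / sma if sma > 0 else 0.0
    return out


def bf_cumulative_frequency(freqs, psd, fraction):
    """Smallest grid frequency whose cumulative power reaches the given
    fraction of total in-band power (linear scan)."""
    total = sum(psd)
    running = 0.0
    for f, p in zip(freqs, psd):
        running += p
        if running >= fraction * total:
            return f
    return freqs[-1]


def bf_shapley(predict, x, background):
    """Exact Shapley values of one sample by direct subset enumeration.

    ``predict`` maps a (m, p) matrix to (m,) outputs; the value of a
    coalition S is the background-average of predictions with S taken
    from ``x``.
    """
    x = np.asarray(x, float)
    background = np.atleast_2d(np.asarray(background, float))
    p = len(x)

    def value(subset):
        rows = []
        for b in background:
            z = b.copy()
            for j in subset:
                z[j] = x[j]
            rows.append(z)
        return float(np.mean(predict(np.asarray(rows))))

    phi = np.zeros(p)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        for size in range(p):
            for subset in combinations(others, size):
                w = (
                    math.factorial(size)
                    * math.factorial(p - size - 1)
                    / math.factorial(p)
                )
                phi[i] += w * (value(subset + (i,)) - value(subset))
    return phi
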