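"""The 76-measure postural-sway feature battery.

The battery is a fixed, ordered schema of 76 named measures computed from
one trial's :class:`~imusway.signal_prep.SwaySignals`: 43 time-domain and
33 frequency-domain values.  Axis expansion rules:

* MDIST, TOTEX, NPL, MVELO, RMS, RMS-G, SPEC-ENTROPY, SPEC-ENTROPY-G and
  MFREQ are computed for the SVM series and each of ML, V, AP (9 x 4 = 36);
* TP, SEF, SEF-G, MED, PEAK, C-FREQ, FREQ-D, SAA and R-SAA-SMA are computed
  per axis ML, V, AP (9 x 3 = 27);
* R (range) and JERK occupy four slots each: the SVM series plus the
  AP-ML, ML-V and AP-V planes (2 x 4 = 8);
* AAMV, AREA-CC, AREA-CE, AREA-SW and SMA are single-slot (5).

Area measures are computed on the AP-ML plane (the horizontal sway plane).
All spectral measures use a Welch periodogram (Hann window, 256-sample
segments, 50% overlap) restricted to the (0, 5] Hz band with the DC bin
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .errors import ExtractionError, SpectralError
from .signal_prep import SwaySignals

__all__ = [
    "FeatureVector",
    "SpectralEstimate",
    "feature_names",
    "feature_domains",
    "extract_features",
    "time_measures",
    "confidence_areas",
    "psd_estimate",
    "spectral_measures",
    "path_length",
]

AXES4 = ("SVM", "ML", "V", "AP")
AXES3 = ("ML", "V", "AP")
PLANES4 = ("SVM", "AP-ML", "ML-V", "AP-V")

WELCH_NPERSEG = 256
SPECTRAL_BAND = (0.0, 5.0)  # Hz, DC bin excluded


def _build_schema() -> list[tuple[str, str]]:
    schema: list[tuple[str, str]] = []

    def add(base: str, suffixes, domain: str) -> None:
        for s in suffixes:
            schema.append((f"{base}-{s}" if s else base, domain))

    add("MDIST", AXES4, "time")          # 0-3
    add("AAMV", [""], "time")            # 4
    add("TOTEX", AXES4, "time")          # 5-8
    add("NPL", AXES4, "time")            # 9-12
    add("MVELO", AXES4, "time")          # 13-16
    add("R", PLANES4, "time")            # 17-20
    add("RMS", AXES4, "time")            # 21-24
    add("RMS-G", AXES4, "time")          # 25-28
    add("AREA-CC", [""], "time")         # 29
    add("AREA-CE", [""], "time")         # 30
    add("AREA-SW", [""], "time")         # 31
    add("JERK", PLANES4, "time")         # 32-35
    add("TP", AXES3, "frequency")        # 36-38
    add("SEF", AXES3, "frequency")       # 39-41
    add("SEF-G", AXES3, "frequency")     # 42-44
    add("MED", AXES3, "frequency")       # 45-47
    add("PEAK", AXES3, "frequency")      # 48-50
    add("C-FREQ", AXES3, "frequency")    # 51-53
    add("FREQ-D", AXES3, "frequency")    # 54-56
    add("SPEC-ENTROPY", AXES4, "frequency")    # 57-60
    add("SPEC-ENTROPY-G", AXES4, "frequency")  # 61-64
    add("SAA", AXES3, "time")            # 65-67
    add("SMA", [""], "time")             # 68
    add("R-SAA-SMA", AXES3, "time")      # 69-71
    add("MFREQ", AXES4, "frequency")     # 72-75
    return schema


_SCHEMA = _build_schema()
assert len(_SCHEMA) == 76


def feature_names() -> list[str]:
    """The 76 feature names in schema (index 0-75) order."""
    return [name for name, _ in _SCHEMA]


def feature_domains() -> dict[str, str]:
    """Map feature name -> 'time' | 'frequency'."""
    return dict(_SCHEMA)


@dataclass
class FeatureVector:
    """The 76 named sway measures for one trial, in schema order."""

    values: dict[str, float]
    subject_id: str = ""
    session: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        expected = feature_names()
        if list(self.values.keys()) != expected:
            raise ExtractionError(
                "feature vector does not match the 76-entry schema"
            )

    def to_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in feature_names()])

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class SpectralEstimate:
    """Welch PSD restricted bookkeeping for spectral moment measures."""

    freqs: np.ndarray
    psd: np.ndarray
    resolution: float
    band: tuple[float, float]

    def __post_init__(self) -> None:
        if np.any(self.psd < 0):
            raise SpectralError("psd must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise SpectralError("frequency grid must be strictly increasing")

    def in_band(self) -> tuple[np.ndarray, np.ndarray]:
        """Frequencies and psd inside (band_lo, band_hi], DC excluded."""
        lo, hi = self.band
        mask = (self.freqs > lo) & (self.freqs <= hi)
        return self.freqs[mask], self.psd[mask]


def path_length(points: np.ndarray) -> float:
    """Total excursion: sum of Euclidean distances between consecutive
    points.  ``points`` is (N, d) for planar/3-D paths or (N,) for a
    scalar series."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        return float(np.sum(np.abs(np.diff(points))))
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def _jerk(x: np.ndarray, fs: float) -> float:
    """Time integral of the squared first derivative: sum((da/dt)^2) * dt."""
    dt = 1.0 / fs
    d = np.diff(x) / dt
    return float(np.sum(d**2) * dt)


def time_measures(s: SwaySignals) -> dict[str, float]:
    """All 43 time-domain measures.

    Per-axis distance measures treat each demeaned axis as a scalar series
    (|x(n)| distances); SVM slots apply the same scalar definition to the
    svm magnitude series (for RMS-G and SPEC-ENTROPY-G slots, the gyro
    magnitude series).  Planar slots use Euclidean point distances.
    """
    if s.n_samples < 2:
        raise ExtractionError("time measures need at least 2 samples")
    out: dict[str, float] = {}
    T = s.duration_s
    n = s.n_samples
    axes = {"SVM": s.svm, "ML": s.ml, "V": s.v, "AP": s.ap}
    gyro = {"SVM": s.gsvm, "ML": s.gml, "V": s.gv, "AP": s.gap}
    planes = {
        "AP-ML": np.column_stack([s.ap, s.ml]),
        "ML-V": np.column_stack([s.ml, s.v]),
        "AP-V": np.column_stack([s.ap, s.v]),
    }

    for ax, x in axes.items():
        out[f"MDIST-{ax}"] = float(np.mean(np.abs(x)))
        totex = path_length(x)
        out[f"TOTEX-{ax}"] = totex
        out[f"NPL-{ax}"] = totex / n
        out[f"MVELO-{ax}"] = totex / T
        out[f"RMS-{ax}"] = _rms(x)
        out[f"RMS-G-{ax}"] = _rms(gyro[ax])

    out["AAMV"] = float(np.mean(np.abs(s.svm - np.mean(s.svm))))

    out["R-SVM"] = float(np.ptp(s.svm))
    out["JERK-SVM"] = _jerk(s.svm, s.fs)
    for pl, pts in planes.items():
        r = np.ptp(pts, axis=0)
        out[f"R-{pl}"] = float(np.hypot(r[0], r[1]))
        out[f"JERK-{pl}"] = _jerk(pts[:, 0], s.fs) + _jerk(pts[:, 1], s.fs)

    out.update(confidence_areas(s.ml, s.ap, s.fs))

    sma = float(np.mean(np.abs(s.ml) + np.abs(s.v) + np.abs(s.ap)))
    out["SMA"] = sma
    for ax in AXES3:
        saa = float(np.sum(axes[ax]))
        out[f"SAA-{ax}"] = saa
        out[f"R-SAA-SMA-{ax}"] = saa / sma if sma > 0 else 0.0
    return out


def confidence_areas(ml: np.ndarray, ap: np.ndarray, fs: float) -> dict[str, float]:
    """AREA-CC, AREA-CE and AREA-SW on the AP-ML plane.

    * AREA-CC: circle of radius mean(RD) + 1.645 sd(RD) where RD is the
      per-sample planar radial distance (covers ~95% of distances under
      normality).
    * AREA-CE: 95% bivariate confidence ellipse,
      2 pi F(2, N-2; 0.95) sqrt(s_ap^2 s_ml^2 - s_apml^2).
    * AREA-SW: area swept by the trajectory per unit time,
      (1 / 2T) sum |ap(n+1) ml(n) - ap(n) ml(n+1)|.

    A degenerate (zero-variance) plane yields zero areas, not an error.
    """
    ml = np.asarray(ml, dtype=float)
    ap = np.asarray(ap, dtype=float)
    n = ml.shape[0]
    if n < 3:
        raise ExtractionError("confidence areas need at least 3 samples")
    rd = np.hypot(ml, ap)
    mdist = float(np.mean(rd))
    sd_rd = float(np.std(rd, ddof=1))
    area_cc = np.pi * (mdist + 1.645 * sd_rd) ** 2

    s_ml2 = float(np.var(ml, ddof=1))
    s_ap2 = float(np.var(ap, ddof=1))
    s_apml = float(np.cov(ap, ml, ddof=1)[0, 1])
    det = s_ap2 * s_ml2 - s_apml**2
    if det <= 0:
        area_ce = 0.0
    else:
        f95 = spstats.f.ppf(0.95, 2, n - 2)
        area_ce = 2 * np.pi * f95 * float(np.sqrt(det))

    T = n / fs
    cross = np.abs(ap[1:] * ml[:-1] - ap[:-1] * ml[1:])
    area_sw = float(np.sum(cross) / (2 * T))
    return {"AREA-CC": float(area_cc), "AREA-CE": float(area_ce), "AREA-SW": area_sw}


def psd_estimate(
    series: np.ndarray,
    fs: float,
    nperseg: int = WELCH_NPERSEG,
    band: tuple[float, float] = SPECTRAL_BAND,
) -> SpectralEstimate:
    """Welch average periodogram (Hann window, 50% overlap, density
    scaling) with the analysis band attached."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] < nperseg:
        raise SpectralError(
            f"series of length {series.shape[0]} shorter than one "
            f"{nperseg}-sample segment"
        )
    freqs, psd = sps.welch(
        series,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        scaling="density",
        detrend=False,
    )
    return SpectralEstimate(
        freqs=freqs, psd=psd, resolution=float(freqs[1] - freqs[0]), band=band
    )


def spectral_measures(spec: SpectralEstimate) -> dict[str, float]:
    """Moment-based spectral measures of one PSD estimate.

    With in-band moments mu_k = sum f^k psd(f) df:
    TP = mu_0, MFREQ = mu_1/mu_0, C-FREQ = sqrt(mu_2/mu_0),
    FREQ-D = sqrt(1 - mu_1^2/(mu_0 mu_2)); SEF/MED are the smallest grid
    frequencies whose cumulative in-band power reaches 95% / 50% of TP;
    PEAK is the argmax frequency; entropy is the normalized Shannon
    entropy of the in-band power distribution (in [0, 1]).  Zero total
    power maps every measure to 0 by convention.
    """
    f, p = spec.in_band()
    df = spec.resolution
    mu0 = float(np.sum(p) * df)
    if mu0 <= 0 or f.size == 0:
        return {k: 0.0 for k in
                ("TP", "SEF", "MED", "PEAK", "C-FREQ", "FREQ-D", "MFREQ", "ENTROPY")}
    mu1 = float(np.sum(f * p) * df)
    mu2 = float(np.sum(f**2 * p) * df)
    cum = np.cumsum(p) * df
    sef = float(f[np.searchsorted(cum, 0.95 * mu0)])
    med = float(f[np.searchsorted(cum, 0.50 * mu0)])
    peak = float(f[np.argmax(p)])
    cfreq = float(np.sqrt(mu2 / mu0))
    freq_d = float(np.sqrt(max(0.0, 1.0 - mu1**2 / (mu0 * mu2))))
    mfreq = mu1 / mu0
    prob = p / np.sum(p)
    nz = prob[prob > 0]
    k = prob.size
    entropy = float(-np.sum(nz * np.log(nz)) / np.log(k)) if k > 1 else 0.0
    return {
        "TP": mu0,
        "SEF": sef,
        "MED": med,
        "PEAK": peak,
        "C-FREQ": cfreq,
        "FREQ-D": freq_d,
        "MFREQ": mfreq,
        "ENTROPY": entropy,
    }


def extract_features(
    s: SwaySignals, min_duration_s: float = 10.0
) -> FeatureVector:
    """Compute the full 76-measure battery for one trial."""
    if s.duration_s < min_duration_s:
        raise ExtractionError(
            f"trial of {s.duration_s:.2f} s shorter than the "
            f"{min_duration_s:g} s minimum (all measures)"
        )
    tm = time_measures(s)

    acc_channels = {"SVM": s.svm, "ML": s.ml, "V": s.v, "AP": s.ap}
    gyr_channels = {"SVM": s.gsvm, "ML": s.gml, "V": s.gv, "AP": s.gap}
    try:
        acc_spec = {ax: spectral_measures(psd_estimate(x, s.fs))
                    for ax, x in acc_channels.items()}
        gyr_spec = {ax: spectral_measures(psd_estimate(x, s.fs))
                    for ax, x in gyr_channels.items()}
    except SpectralError as exc:
        raise ExtractionError(f"spectral measures failed: {exc}") from exc

    fm: dict[str, float] = {}
    for ax in AXES3:
        fm[f"TP-{ax}"] = acc_spec[ax]["TP"]
        fm[f"SEF-{ax}"] = acc_spec[ax]["SEF"]
        fm[f"SEF-G-{ax}"] = gyr_spec[ax]["SEF"]
        fm[f"MED-{ax}"] = acc_spec[ax]["MED"]
        fm[f"PEAK-{ax}"] = acc_spec[ax]["PEAK"]
        fm[f"C-FREQ-{ax}"] = acc_spec[ax]["C-FREQ"]
        fm[f"FREQ-D-{ax}"] = acc_spec[ax]["FREQ-D"]
    for ax in AXES4:
        fm[f"SPEC-ENTROPY-{ax}"] = acc_spec[ax]["ENTROPY"]
        fm[f"SPEC-ENTROPY-G-{ax}"] = gyr_spec[ax]["ENTROPY"]
        fm[f"MFREQ-{ax}"] = acc_spec[ax]["MFREQ"]

    merged = {**tm, **fm}
    values = {name: float(merged[name]) for name in feature_names()}
    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise ExtractionError(f"non-finite measures: {bad}")
    return FeatureVector(
        values=values, subject_id=s.subject_id, session=s.session, trial=s.trial
    )


import pandas as pd  # noqa: E402  (table helpers only)

ID_COLUMNS = ["subject_id", "session", "trial"]


def features_to_frame(fvs: list[FeatureVector]) -> pd.DataFrame:
    """Wide table: one row per trial, ID columns + 76 feature columns."""
    rows = []
    for fv in fvs:
        row = {"subject_id": fv.subject_id, "session": fv.session, "trial": fv.trial}
        row.update(fv.values)
        rows.append(row)
    return pd.DataFrame(rows, columns=ID_COLUMNS + feature_names())


def features_to_long(fvs: list[FeatureVector]) -> pd.DataFrame:
    """Long table: subject_id, session, trial, feature, value."""
    wide = features_to_frame(fvs)
    return wide.melt(
        id_vars=ID_COLUMNS, var_name="feature", value_name="value"
    )
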