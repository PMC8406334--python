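"""Single-cell metabolism-related phenotypes derived from Raman spectra.

Each spectral position can proxy a metabolite pool: e.g. 940 cm^-1
(C-O stretching) tracks starch and 2851 cm^-1 (C-H2 stretches) tracks
triacylglycerol (TAG) in microalgae. Beyond single peaks, composite
phenotypes combine several features:

* DU ratio — degree of lipid unsaturation, I(1658)/I(1441), the ratio of
  the unsaturated C=C stretch to the saturated C-H2 bend;
* CD ratio — fraction of the carbon-deuterium band area (2040-2300 cm^-1)
  over C-D plus C-H areas (adding 2800-3050 cm^-1), a proxy for heavy
  water (D2O) metabolic incorporation;
* PLSR content models — partial least squares regressions mapping full
  spectra to metabolite contents, trained on bulk measurements paired
  with population-mean spectra.

Per-ramanome heterogeneity is summarized by the heterogeneity index (HI),
the relative standard deviation of a feature across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from irca.core import DegenerateInputError, IrcaError, Ramanome, Spectrum
from irca.preprocess import trapezoid_area

__all__ = [
    "MARKER_TABLE", "PhenotypeDef", "PLSRModel", "ContentSummary",
    "peak_intensity", "band_area", "du_ratio", "cd_ratio",
    "phenotype_matrix", "heterogeneity_index", "content_summary",
    "plsr_fit", "plsr_predict", "marker_feature_matrix",
    "CD_BAND", "CH_BAND",
]

#: Characteristic marker peaks (cm^-1) by biomolecular class, used for
#: reduced marker-level networks and as band centers by the synthetic
#: generator.
MARKER_TABLE: dict[str, tuple[float, ...]] = {
    "nucleic_acids": (669, 783, 814, 1481),
    "proteins": (622, 643, 758, 1003, 1176, 1211, 1246, 1584, 1606, 1619),
    "carbohydrates": (865, 940, 1033, 1045, 1127),
    "lipids": (725, 971, 1083, 1265, 1305, 1441, 1450, 1658, 1742),
}

CD_BAND = (2040.0, 2300.0)
CH_BAND = (2800.0, 3050.0)

DU_UNSATURATED = 1658.0
DU_SATURATED = 1441.0


@dataclass(frozen=True)
class PhenotypeDef:
    """A named single-cell phenotype computable from one spectrum.

    kind: 'peak' (params: wavenumber), 'band_area' (params: lo, hi),
    'peak_ratio' (params: numerator, denominator wavenumbers),
    'band_ratio' (params: num_band, den_bands), 'du', 'cd', or
    'plsr' (params: model).
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)


def peak_intensity(s: Spectrum, wavenumber: float, tol: float = 1.0) -> float:
    """Intensity at the grid point nearest ``wavenumber`` (within tol)."""
    return float(s.intensities[s.axis.index_of(wavenumber, tol)])


def band_area(s: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the spectrum over [lo, hi]."""
    if not (lo < hi):
        raise IrcaError("band requires lo < hi")
    if lo < s.axis.lo or hi > s.axis.hi:
        raise IrcaError(
            f"band [{lo}, {hi}] not covered by axis "
            f"[{s.axis.lo}, {s.axis.hi}]"
        )
    mask = (s.axis.wavenumbers >= lo) & (s.axis.wavenumbers <= hi)
    if mask.sum() < 2:
        raise IrcaError(f"band [{lo}, {hi}] covers fewer than 2 grid points")
    return float(np.trapezoid(s.intensities[mask], s.axis.wavenumbers[mask]))


def du_ratio(s: Spectrum) -> float:
    """Degree of lipid unsaturation: I(1658) / I(1441)."""
    num = peak_intensity(s, DU_UNSATURATED)
    den = peak_intensity(s, DU_SATURATED)
    if den == 0:
        raise IrcaError("DU ratio undefined: I(1441) = 0")
    return num / den


def cd_ratio(s: Spectrum) -> float:
    """Deuterium incorporation: A(C-D) / (A(C-D) + A(C-H)).

    Requires an axis covering both the C-D (2040-2300 cm^-1) and C-H
    (2800-3050 cm^-1) bands, i.e. a spectrum that was not cropped to the
    fingerprint region. Lies in [0, 1] for non-negative spectra.
    """
    a_cd = band_area(s, *CD_BAND)
    a_ch = band_area(s, *CH_BAND)
    total = a_cd + a_ch
    if total == 0:
        raise IrcaError("CD ratio undefined: zero total C-D + C-H area")
    return a_cd / total


def _evaluate(s: Spectrum, d: PhenotypeDef) -> float:
    if d.kind == "peak":
        return peak_intensity(s, d.params["wavenumber"])
    if d.kind == "band_area":
        return band_area(s, d.params["lo"], d.params["hi"])
    if d.kind == "peak_ratio":
        den = peak_intensity(s, d.params["denominator"])
        if den == 0:
            raise IrcaError(f"{d.name}: zero denominator peak")
        return peak_intensity(s, d.params["numerator"]) / den
    if d.kind == "du":
        return du_ratio(s)
    if d.kind == "cd":
        return cd_ratio(s)
    if d.kind == "plsr":
        m: PLSRModel = d.params["model"]
        return float(m.predict_one(s))
    raise IrcaError(f"unknown phenotype kind {d.kind!r}")


def phenotype_matrix(r: Ramanome, defs: list[PhenotypeDef]) -> np.ndarray:
    """Cells x phenotypes matrix; column order follows ``defs``."""
    if not defs:
        raise IrcaError("empty phenotype definition list")
    out = np.empty((r.n_cells, len(defs)))
    for j, d in enumerate(defs):
        for i in range(r.n_cells):
            out[i, j] = _evaluate(r.spectrum(i), d)
    return out


def marker_feature_matrix(r: Ramanome,
                          extra_peaks: tuple[float, ...] = (),
                          ) -> tuple[np.ndarray, list[str]]:
    """Cells x marker-peak intensity matrix for reduced marker-level
    networks, with wavenumber string labels.

    Uses every resolvable peak of the marker table plus ``extra_peaks``
    (e.g. 2851 cm^-1 when the axis extends beyond the fingerprint).
    """
    peaks = sorted({w for cls in MARKER_TABLE.values() for w in cls}
                   | set(extra_peaks))
    cols, labels = [], []
    for w in peaks:
        try:
            cols.append(r.peak_column(w))
        except IrcaError:
            continue
        labels.append(f"{w:g}")
    if not cols:
        raise IrcaError("no marker peak resolvable on this axis")
    return np.column_stack(cols), labels


def heterogeneity_index(r: Ramanome) -> np.ndarray:
    """Per-feature relative standard deviation across cells (sample sd).

    HI = sd / |mean|; zero-mean features yield NaN with a warning. HI is
    invariant to a common positive per-feature scaling and is 0 exactly
    when the feature is constant across cells.
    """
    if r.n_cells < 2:
        raise DegenerateInputError("HI needs >= 2 cells")
    mean = r.matrix.mean(axis=0)
    sd = r.matrix.std(axis=0, ddof=1)
    constant = np.ptp(r.matrix, axis=0) == 0
    sd[constant] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        hi = sd / np.abs(mean)
    hi[(sd == 0)] = 0.0
    zero_mean = (mean == 0) & (sd > 0)
    if zero_mean.any():
        warnings.warn(
            f"{int(zero_mean.sum())} zero-mean features; HI set to NaN",
            stacklevel=2,
        )
        hi[zero_mean] = np.nan
    return hi


@dataclass(frozen=True)
class ContentSummary:
    """Range statistics of one phenotype across the cells of a ramanome."""

    min: float
    max: float
    delta: float
    mean: float
    rsd: float


def content_summary(values: np.ndarray) -> ContentSummary:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateInputError("content_summary of empty vector")
    if not np.all(np.isfinite(v)):
        raise IrcaError("content_summary input contains non-finite values")
    mean = float(v.mean())
    sd = (float(v.std(ddof=1))
          if v.size > 1 and np.ptp(v) > 0 else 0.0)
    rsd = sd / abs(mean) if mean != 0 else (0.0 if sd == 0 else np.nan)
    return ContentSummary(
        min=float(v.min()), max=float(v.max()),
        delta=float(v.max() - v.min()), mean=mean, rsd=rsd,
    )


# ---------------------------------------------------------------------------
# PLSR content models
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    """Fitted PLSR mapping spectra to a metabolite content.

    Thin wrapper around a NIPALS partial-least-squares fit with mean
    centering and no variance scaling; prediction is the linear map
    y = (x - x_mean) @ coef + y_mean.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    r2_train: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef + self.y_mean

    def predict_one(self, s: Spectrum) -> float:
        if len(s) != self.x_mean.size:
            raise IrcaError(
                f"model expects {self.x_mean.size} features, spectrum has "
                f"{len(s)}"
            )
        return float(self.predict(s.intensities[None, :])[0])


def plsr_fit(X: np.ndarray, y: np.ndarray,
             n_components: int | None = None) -> PLSRModel:
    """Fit a PLSR content model on training spectra ``X`` and contents ``y``.

    ``X`` is samples x features (typically population-mean spectra paired
    with bulk content measurements). When ``n_components`` is None it is
    chosen by leave-one-out cross-validation maximizing predictive R^2.
    Deterministic for fixed input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise IrcaError("X must be samples x features matching y")
    n, f = X.shape
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise IrcaError("PLSR training data must be finite")
    if np.std(y) == 0:
        raise IrcaError("zero-variance training contents")
    k_max = min(n - 1, f)
    if n_components is None:
        n_components = _loo_best_k(X, y, k_max)
    if not 1 <= n_components <= k_max:
        raise IrcaError(
            f"n_components={n_components} out of range [1, {k_max}] for "
            f"{n} samples x {f} features"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    coef = pls.coef_.reshape(-1)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    pred = (X - x_mean) @ coef + y_mean
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y_mean) ** 2))
    return PLSRModel(
        n_components=int(n_components), x_mean=x_mean, y_mean=y_mean,
        coef=coef, r2_train=1.0 - ss_res / ss_tot,
    )


def _loo_best_k(X: np.ndarray, y: np.ndarray, k_max: int) -> int:
    n = X.shape[0]
    best_k, best_press = 1, np.inf
    with warnings.catch_warnings():
        # exploring k beyond the effective rank is expected during CV
        warnings.simplefilter("ignore")
        for k in range(1, min(k_max, 10) + 1):
            press = 0.0
            for i in range(n):
                mask = np.arange(n) != i
                if k > min(n - 2, X.shape[1]):
                    press = np.inf
                    break
                pls = PLSRegression(n_components=k, scale=False)
                pls.fit(X[mask], y[mask])
                press += float(
                    (pls.predict(X[i:i + 1]).ravel()[0] - y[i]) ** 2)
            if press < best_press - 1e-12:
                best_press, best_k = press, k
    return best_k


def plsr_predict(m: PLSRModel, r: Ramanome) -> np.ndarray:
    """Apply a fitted content model to every cell of a ramanome."""
    if r.n_features != m.x_mean.size:
        raise IrcaError(
            f"model expects {m.x_mean.size} features, ramanome has "
            f"{r.n_features}"
        )
    return m.predict(r.matrix)
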