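"""Synthetic ramanome generator with planted conversion structure.

Real ramanome datasets are rarely deposited, so validation here rests on
an emulator: each synthetic cell's spectrum is a non-negative mixture of
biomolecular component spectra (protein, starch/carbohydrate, saturated
and unsaturated lipid, nucleic acid, the PS/PI membrane lipids, and an
optional carbon-deuterium label band), plus an optional polynomial
baseline and noise. Per-cell component amplitudes are drawn from a
lognormal model with a *planted* correlation structure (a Gaussian
copula): e.g. a latent starch-TAG correlation of -0.8 emulates a
population in which cells converting starch into TAG coexist with cells
that have not yet switched. The planted structure — not biology — is the
ground truth that downstream network recovery is tested against.

Trajectory presets schedule the component means and planted correlations
over time, emulating the canonical nitrogen-starvation course of a
starch-accumulating microalga: protein degrades into starch early
(protein-starch negative correlation), starch converts into
triacylglycerol late (starch-TAG negative correlation), membrane lipids
feed TAG in parallel; a "starchless" preset knocks the carbohydrate
component out entirely, and a D2O-labeling preset couples the C-D band
to TAG at intermediate times only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from irca.core import IrcaError, CellMeta, Ramanome, RamanomeSeries, SpectralAxis

__all__ = [
    "COMPONENT_BANDS", "COMPONENT_ORDER", "ComponentSpectrum", "StateConfig",
    "TrajectoryPreset", "get_preset", "default_axis",
    "make_component_spectra", "sample_latent_contents", "render_ramanome",
    "simulate_ramanome", "simulate_series", "PRESET_NAMES",
]

#: Gaussian band centers (cm^-1) and relative heights per component,
#: assembled from characteristic marker assignments: e.g. 478/940 cm^-1
#: for starch, 1441/2851 cm^-1 for saturated (storage) lipid,
#: 1658 cm^-1 for unsaturated C=C, 526/577 cm^-1 for the PS/PI membrane
#: lipids, and a broad 2040-2300 cm^-1 hump for C-D label.
COMPONENT_BANDS: dict[str, tuple[tuple[float, float], ...]] = {
    "protein": (
        (622, 0.5), (643, 0.5), (758, 0.7), (1003, 2.0), (1176, 0.5),
        (1211, 0.6), (1246, 0.8), (1584, 0.6), (1606, 0.7), (1619, 0.7),
        (2935, 1.2),
    ),
    "carbohydrate": (
        (478, 0.8), (865, 0.5), (938, 1.0), (940, 1.0), (1033, 0.5),
        (1045, 0.6), (1127, 0.7),
    ),
    "lipid_sat": (
        (1083, 0.4), (1265, 0.4), (1305, 0.7), (1441, 1.0), (1450, 0.8),
        (1742, 0.5), (2851, 1.5), (2855, 1.5),
    ),
    "lipid_unsat": (
        (971, 0.3), (1265, 0.6), (1658, 1.0), (3011, 0.8),
    ),
    "nucleic_acid": (
        (669, 0.8), (783, 1.0), (814, 0.8), (1481, 0.9),
    ),
    "membrane_lipid_PS": (
        (526, 1.0), (968, 0.4), (1083, 0.6),
    ),
    "membrane_lipid_PI": (
        (577, 1.0), (725, 0.4), (1083, 0.6),
    ),
    "cd_label": (
        (2170, 1.0),
    ),
}

COMPONENT_ORDER = tuple(COMPONENT_BANDS)

#: Default full-width-at-half-maximum of a band, cm^-1 (typical Raman
#: linewidth); the C-D hump is much broader.
DEFAULT_FWHM = 8.0
CD_FWHM = 120.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def default_axis(lo: float = 450.0, hi: float = 3100.0,
                 step: float = 1.0) -> SpectralAxis:
    """Default acquisition grid: 450-3100 cm^-1 at 1 cm^-1, covering the
    fingerprint region plus the C-D and C-H high-wavenumber bands."""
    n = int(round((hi - lo) / step)) + 1
    return SpectralAxis(lo + step * np.arange(n))


@dataclass(frozen=True)
class ComponentSpectrum:
    """Unit-area, non-negative spectrum of one biomolecular component."""

    name: str
    axis: SpectralAxis
    intensities: np.ndarray


def make_component_spectra(axis: SpectralAxis,
                           names: tuple[str, ...] = COMPONENT_ORDER,
                           fwhm: float = DEFAULT_FWHM,
                           ) -> list[ComponentSpectrum]:
    """Render each component as a sum of Gaussian bands on ``axis``.

    Bands outside the axis range are dropped with a warning; a component
    with no band in range raises. Each component is normalized to unit
    trapezoidal area so amplitudes are directly comparable.
    """
    w = axis.wavenumbers
    out = []
    for name in names:
        if name not in COMPONENT_BANDS:
            raise IrcaError(f"unknown component {name!r}")
        y = np.zeros_like(w)
        n_in = 0
        for center, height in COMPONENT_BANDS[name]:
            if not (axis.lo <= center <= axis.hi):
                warnings.warn(
                    f"{name}: band {center} cm^-1 outside axis "
                    f"[{axis.lo}, {axis.hi}]; dropped", stacklevel=2,
                )
                continue
            width = CD_FWHM if name == "cd_label" else fwhm
            sigma = width * _FWHM_TO_SIGMA
            y += height * np.exp(-0.5 * ((w - center) / sigma) ** 2)
            n_in += 1
        if n_in == 0:
            raise IrcaError(
                f"component {name!r} has no band inside axis "
                f"[{axis.lo}, {axis.hi}]"
            )
        area = np.trapezoid(y, w)
        out.append(ComponentSpectrum(name, axis, y / area))
    return out


@dataclass(frozen=True)
class StateConfig:
    """One population state: component means, planted correlations, noise.

    component_means: expected amplitude per component (a knockout is a
    zero mean). latent_corr: planted pairwise correlations of the latent
    Gaussian (equivalently, of log-amplitudes); unlisted pairs are 0.
    amplitude_sigma: lognormal dispersion of per-cell amplitudes
    (sigma of log-amplitude; 0.25 emulates the ~25% cell-to-cell RSD
    typical of metabolite contents). noise_additive: additive Gaussian sd
    as a fraction of the mean clean spectrum's maximum. noise_mult: sd of
    the per-cell multiplicative lognormal factor (deliberately removable
    by area normalization). baseline_coeffs: polynomial coefficients
    (low to high order, on the axis scaled to [-1, 1]).
    """

    component_means: dict[str, float]
    latent_corr: dict[tuple[str, str], float] = field(default_factory=dict)
    amplitude_sigma: float = 0.25
    noise_additive: float = 0.05
    noise_mult: float = 0.1
    baseline_coeffs: tuple[float, ...] = ()

    def components(self) -> tuple[str, ...]:
        return tuple(self.component_means)

    def corr(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.latent_corr.get((a, b), self.latent_corr.get((b, a), 0.0))

    def corr_matrix(self) -> np.ndarray:
        names = self.components()
        k = len(names)
        R = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                R[i, j] = R[j, i] = self.corr(names[i], names[j])
        return R


def sample_latent_contents(sc: StateConfig, n_cells: int,
                           seed: int | np.random.Generator | None = None,
                           ) -> np.ndarray:
    """Draw per-cell component amplitudes from the planted lognormal model.

    A latent Gaussian vector with the planted correlation matrix is
    drawn per cell (Gaussian copula); amplitudes are
    mean_c * exp(sigma * z_c), so they are non-negative, their
    log-correlations equal the planted matrix, and knockout components
    (zero mean) are exactly 0.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    names = sc.components()
    R = sc.corr_matrix()
    eigvals = np.linalg.eigvalsh(R)
    if eigvals[0] < -1e-10:
        raise IrcaError(
            f"planted correlation matrix is not positive semidefinite "
            f"(smallest eigenvalue {eigvals[0]:.4g})"
        )
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(names)))
    z = rng.standard_normal((n_cells, len(names))) @ L.T
    means = np.array([sc.component_means[n] for n in names])
    amps = means * np.exp(sc.amplitude_sigma * z)
    amps[:, means == 0] = 0.0
    return amps


def render_ramanome(amplitudes: np.ndarray,
                    components: list[ComponentSpectrum],
                    sc: StateConfig,
                    axis: SpectralAxis,
                    seed: int | np.random.Generator | None = None,
                    ramanome_id: str = "synthetic",
                    meta: dict | None = None) -> Ramanome:
    """Mix amplitudes with component spectra, add baseline and noise.

    cell spectrum = sum_c amplitude[c] * component_c
                    + baseline polynomial + additive Gaussian noise,
    all scaled by a per-cell multiplicative lognormal factor and clipped
    at 0. The generator truth (amplitudes, planted correlations) is
    stored in the ramanome's metadata for test oracles.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    A = np.asarray(amplitudes, dtype=float)
    C = np.vstack([c.intensities for c in components])
    if A.shape[1] != C.shape[0]:
        raise IrcaError(
            f"{A.shape[1]} amplitude columns for {C.shape[0]} components"
        )
    clean = A @ C
    w = axis.wavenumbers
    if sc.baseline_coeffs:
        x = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
        clean = clean + np.polynomial.polynomial.polyval(
            x, np.asarray(sc.baseline_coeffs))
    scale = clean.mean(axis=0).max()
    noisy = clean + rng.standard_normal(clean.shape) * (
        sc.noise_additive * scale)
    if sc.noise_mult > 0:
        factor = np.exp(rng.standard_normal(A.shape[0]) * sc.noise_mult)
        noisy = noisy * factor[:, None]
    matrix = np.clip(noisy, 0.0, None)
    md = dict(meta or {})
    md.setdefault("ramanome_id", ramanome_id)
    md["truth"] = {
        "component_names": [c.name for c in components],
        "amplitudes": A,
        "latent_corr": dict(sc.latent_corr),
        "component_means": dict(sc.component_means),
    }
    cells = [CellMeta(f"cell_{i:04d}", str(md["ramanome_id"]))
             for i in range(A.shape[0])]
    return Ramanome(axis, matrix, cells, md)


def simulate_ramanome(sc: StateConfig, n_cells: int = 60,
                      axis: SpectralAxis | None = None,
                      seed: int | np.random.Generator | None = None,
                      ramanome_id: str = "synthetic",
                      meta: dict | None = None) -> Ramanome:
    """Sample amplitudes and render one ramanome in one call."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if axis is None:
        axis = default_axis()
    comps = make_component_spectra(axis, sc.components())
    amps = sample_latent_contents(sc, n_cells, rng)
    return render_ramanome(amps, comps, sc, axis, rng,
                           ramanome_id=ramanome_id, meta=meta)


# ---------------------------------------------------------------------------
# trajectory presets
# ---------------------------------------------------------------------------

def _means(protein, carb, sat, unsat, nucleic, ps, pi, cd=0.0) -> dict[str, float]:
    return {
        "protein": protein, "carbohydrate": carb, "lipid_sat": sat,
        "lipid_unsat": unsat, "nucleic_acid": nucleic,
        "membrane_lipid_PS": ps, "membrane_lipid_PI": pi, "cd_label": cd,
    }


def _factor_corr(loadings: dict[str, float]) -> dict[tuple[str, str], float]:
    """Pairwise correlations implied by a single latent progression axis.

    Cells in one snapshot sit at different stages of the same conversion
    process; a component with loading lambda_c co-varies with that
    progression, giving rho(a, b) = lambda_a * lambda_b. The implied
    correlation matrix is positive semidefinite by construction.
    """
    names = [n for n, v in loadings.items() if v != 0.0]
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[(a, b)] = round(loadings[a] * loadings[b], 4)
    return out


#: Nitrogen-starvation schedule of a starch-accumulating microalga:
#: protein falls while starch rises early (planted protein-carbohydrate
#: NC), then starch plateaus and storage lipid rises late. The late
#: anchors derive their correlation structure from a single progression
#: axis whose loadings reproduce the headline pair values
#: (starch-TAG -0.8, membrane-TAG -0.6, protein-saturated-lipid -0.5).
_PST_SCHEDULE: tuple[tuple[float, StateConfig], ...] = (
    # protein degrades into starch through the first day (strong
    # protein-carbohydrate NC from the start); cells carry baseline starch
    (0.0, StateConfig(
        component_means=_means(1.0, 0.3, 0.10, 0.08, 0.25, 0.25, 0.25),
        latent_corr={("protein", "carbohydrate"): -0.7},
    )),
    (24.0, StateConfig(
        component_means=_means(0.6, 0.9, 0.2, 0.12, 0.2, 0.22, 0.22),
        latent_corr={
            ("protein", "carbohydrate"): -0.6,
            ("carbohydrate", "lipid_sat"): -0.3,
            ("membrane_lipid_PS", "lipid_sat"): -0.3,
            ("membrane_lipid_PI", "lipid_sat"): -0.3,
            ("membrane_lipid_PS", "membrane_lipid_PI"): 0.3,
        },
    )),
    (96.0, StateConfig(
        component_means=_means(0.4, 1.0, 0.55, 0.25, 0.15, 0.18, 0.18),
        latent_corr=_factor_corr({
            "protein": -0.5, "carbohydrate": -0.8, "lipid_sat": 0.88,
            "lipid_unsat": 0.5, "membrane_lipid_PS": -0.6,
            "membrane_lipid_PI": -0.6,
        }),
    )),
    # late state: starch->TAG conversion at full strength, membrane
    # lipids feeding TAG in parallel, protein converting to lipid
    (192.0, StateConfig(
        component_means=_means(0.3, 0.85, 0.95, 0.45, 0.12, 0.15, 0.15),
        latent_corr=_factor_corr({
            "protein": -0.55, "carbohydrate": -0.88, "lipid_sat": 0.91,
            "lipid_unsat": 0.55, "membrane_lipid_PS": -0.66,
            "membrane_lipid_PI": -0.66,
        }),
    )),
)


def _knockout(sc: StateConfig, name: str) -> StateConfig:
    means = dict(sc.component_means)
    means[name] = 0.0
    corr = {pair: r for pair, r in sc.latent_corr.items() if name not in pair}
    return replace(sc, component_means=means, latent_corr=corr)


_STARCHLESS_SCHEDULE = tuple(
    (t, _knockout(sc, "carbohydrate")) for t, sc in _PST_SCHEDULE
)

_MEMBRANE_SCHEDULE: tuple[tuple[float, StateConfig], ...] = (
    (0.0, StateConfig(
        component_means=_means(0.8, 0.3, 0.15, 0.1, 0.2, 0.35, 0.35),
        latent_corr={},
    )),
    (96.0, StateConfig(
        component_means=_means(0.6, 0.35, 0.7, 0.2, 0.15, 0.2, 0.2),
        latent_corr={
            ("membrane_lipid_PS", "lipid_sat"): -0.7,
            ("membrane_lipid_PI", "lipid_sat"): -0.6,
        },
    )),
)

_D2O_SCHEDULE: tuple[tuple[float, StateConfig], ...] = (
    (0.0, StateConfig(
        component_means=_means(0.9, 0.3, 0.15, 0.1, 0.2, 0.2, 0.2, cd=0.02),
        latent_corr={("protein", "carbohydrate"): -0.6},
    )),
    (48.0, StateConfig(
        component_means=_means(0.6, 0.7, 0.4, 0.15, 0.15, 0.18, 0.18, cd=0.4),
        latent_corr={
            ("carbohydrate", "lipid_sat"): -0.4,
            ("cd_label", "lipid_sat"): -0.7,
        },
    )),
    (96.0, StateConfig(
        component_means=_means(0.45, 0.9, 0.6, 0.25, 0.12, 0.16, 0.16, cd=0.5),
        latent_corr={("carbohydrate", "lipid_sat"): -0.7},
    )),
)


@dataclass(frozen=True)
class TrajectoryPreset:
    """A named schedule of population states over time (hours)."""

    name: str
    schedule: tuple[tuple[float, StateConfig], ...]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise IrcaError("preset schedule time points must increase")

    def state_at(self, t: float) -> StateConfig:
        """State at time ``t`` hours, linearly interpolating means,
        planted correlations, dispersion and noise between anchors
        (clamped at the schedule ends)."""
        times = [a for a, _ in self.schedule]
        if t <= times[0]:
            return self.schedule[0][1]
        if t >= times[-1]:
            return self.schedule[-1][1]
        j = int(np.searchsorted(times, t, side="right"))
        (t0, s0), (t1, s1) = self.schedule[j - 1], self.schedule[j]
        f = (t - t0) / (t1 - t0)

        def lerp(a: float, b: float) -> float:
            return (1 - f) * a + f * b

        names = s0.components()
        means = {n: lerp(s0.component_means[n], s1.component_means[n])
                 for n in names}
        pairs = set(s0.latent_corr) | set(s1.latent_corr)
        corr = {}
        for pair in pairs:
            a, b = pair
            v = lerp(s0.corr(a, b), s1.corr(a, b))
            if v != 0.0:
                corr[pair] = v
        return StateConfig(
            component_means=means, latent_corr=corr,
            amplitude_sigma=lerp(s0.amplitude_sigma, s1.amplitude_sigma),
            noise_additive=lerp(s0.noise_additive, s1.noise_additive),
            noise_mult=lerp(s0.noise_mult, s1.noise_mult),
            baseline_coeffs=s0.baseline_coeffs,
        )


_PRESETS: dict[str, TrajectoryPreset] = {
    "pst": TrajectoryPreset("pst", _PST_SCHEDULE),
    "starchless": TrajectoryPreset("starchless", _STARCHLESS_SCHEDULE),
    "complemented": TrajectoryPreset("complemented", _PST_SCHEDULE),
    "membrane_to_tag": TrajectoryPreset("membrane_to_tag", _MEMBRANE_SCHEDULE),
    "d2o_labeling": TrajectoryPreset("d2o_labeling", _D2O_SCHEDULE),
}

PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str) -> TrajectoryPreset:
    try:
        return _PRESETS[name.lower()]
    except KeyError:
        raise IrcaError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None


def simulate_series(preset: TrajectoryPreset | str,
                    time_points: np.ndarray,
                    n_cells: int = 60,
                    replicates: int = 1,
                    seed: int | None = None,
                    axis: SpectralAxis | None = None,
                    ) -> list[RamanomeSeries]:
    """Simulate replicate time series of ramanomes under a preset.

    One master seed spawns a deterministic child seed per (replicate,
    time point), so any single ramanome is reproducible in isolation.
    Returns one ``RamanomeSeries`` per replicate; each ramanome's
    metadata records the generator truth.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    t = np.asarray(time_points, dtype=float)
    if axis is None:
        axis = default_axis()
    comps_cache: dict[tuple[str, ...], list[ComponentSpectrum]] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(replicates * t.size)
    out = []
    for rep in range(replicates):
        rams = []
        for i, ti in enumerate(t):
            sc = preset.state_at(float(ti))
            names = sc.components()
            if names not in comps_cache:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    comps_cache[names] = make_component_spectra(axis, names)
            rng = np.random.default_rng(children[rep * t.size + i])
            amps = sample_latent_contents(sc, n_cells, rng)
            rid = f"{preset.name}_rep{rep}_t{ti:g}h"
            rams.append(render_ramanome(
                amps, comps_cache[names], sc, axis, rng, ramanome_id=rid,
                meta={"condition": preset.name, "time_h": float(ti),
                      "replicate": rep},
            ))
        out.append(RamanomeSeries(rams, t))
    return out
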