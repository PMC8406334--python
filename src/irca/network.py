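"""Intra-ramanome correlation networks (IRCN).

The core of the method: within one ramanome, every pair of spectral
features is correlated *across cells* (Pearson). Cells differ in
metabolic state even in an isogenic population, so a strong negative
correlation between two features — one pool shrinking as another grows,
cell by cell — flags a candidate metabolite conversion, while any
significant correlation flags a candidate metabolic link.

An IRCN is the undirected graph whose nodes are features (wavenumbers
and/or composite phenotypes) and whose edges are the thresholded
correlations; the default conversion criterion is rho <= -0.6 with
two-sided P < 0.05. Topology statistics (node/edge counts, modules,
density, average degree, average PCC) summarize a network; the delta-rho
map (max rho minus min rho over a time series) localizes the dynamic
"hot spots" of conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from irca.core import DegenerateInputError, IrcaError, Ramanome

__all__ = [
    "CorrelationMatrix", "IRCN", "NetworkStats", "DeltaRhoMap",
    "pearson_with_p", "correlation_matrix", "augment_with_phenotypes",
    "build_ircn", "connected_modules", "network_stats", "top_degree_peaks",
    "delta_rho",
]


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test P-value.

    P is computed from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom; |r| = 1 gives P = 0 exactly. Zero variance in either vector
    returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise IrcaError("vectors differ in length")
    if n < 3:
        raise DegenerateInputError("Pearson P-value needs n >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.dot(xd, xd))
    sy = np.sqrt(np.dot(yd, yd))
    if sx == 0 or sy == 0:
        return (np.nan, np.nan)
    r = float(np.dot(xd, yd) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-14:  # exact collinearity up to rounding
        r = 1.0 if r > 0 else -1.0
    p = _p_from_r(np.array([r]), n)[0]
    return r, float(p)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorized two-sided P from the t-transform of Pearson r."""
    r = np.clip(r, -1.0, 1.0)
    p = np.empty_like(r)
    sat = np.abs(r) >= 1.0
    p[sat] = 0.0
    nan = np.isnan(r)
    p[nan] = np.nan
    ok = ~(sat | nan)
    with np.errstate(divide="ignore"):
        t = r[ok] * np.sqrt((n - 2) / (1.0 - r[ok] ** 2))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return p


@dataclass
class CorrelationMatrix:
    """Symmetric rho and P matrices over an ordered feature list.

    Entries for pairs involving a zero-variance feature are NaN; the
    diagonal of rho is 1 and of pval is 1 by convention.
    """

    features: list[str]
    rho: np.ndarray
    pval: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        f = len(self.features)
        if self.rho.shape != (f, f) or self.pval.shape != (f, f):
            raise IrcaError("rho/pval shape must be F x F")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_pairs(self) -> int:
        """Number of unordered feature pairs evaluated, C(F, 2)."""
        f = self.n_features
        return f * (f - 1) // 2

    def pair(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.features.index(a), self.features.index(b)
        return float(self.rho[i, j]), float(self.pval[i, j])


def feature_labels_from_axis(wavenumbers: np.ndarray) -> list[str]:
    return [np.format_float_positional(w, trim="-") for w in wavenumbers]


def correlation_matrix(features_matrix: np.ndarray,
                       features: list[str] | None = None) -> CorrelationMatrix:
    """All-pairs Pearson correlation of features across cells.

    ``features_matrix`` is cells x features; every unordered pair of
    columns is correlated over the same cell set, C(F, 2) pairs in total.
    Constant columns are flagged with a warning and produce NaN entries
    for every pair they take part in.
    """
    X = np.asarray(features_matrix, dtype=float)
    if X.ndim != 2:
        raise IrcaError("features_matrix must be cells x features")
    n, f = X.shape
    if n < 3:
        raise DegenerateInputError("correlation needs >= 3 cells")
    if features is None:
        features = [f"f{j}" for j in range(f)]
    if len(features) != f:
        raise IrcaError("feature label count does not match matrix")

    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant features; their pairs are NaN",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.corrcoef(X, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    pval = _p_from_r(rho, n)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 1.0)
    return CorrelationMatrix(list(features), rho, pval, n)


def augment_with_phenotypes(features_matrix: np.ndarray,
                            features: list[str],
                            r: Ramanome,
                            defs: list) -> tuple[np.ndarray, list[str]]:
    """Append composite-phenotype columns (e.g. DU, CD ratio) as features.

    The returned matrix and label list feed ``correlation_matrix``
    directly; downstream the new columns are ordinary network nodes.
    """
    from irca.phenotypes import phenotype_matrix

    X = np.asarray(features_matrix, dtype=float)
    if X.shape[0] != r.n_cells:
        raise IrcaError("features_matrix rows must match ramanome cells")
    extra = phenotype_matrix(r, defs)
    labels = list(features) + [d.name for d in defs]
    if len(set(labels)) != len(labels):
        raise IrcaError("duplicate feature labels after augmentation")
    return np.hstack([X, extra]), labels


# ---------------------------------------------------------------------------
# network construction and statistics
# ---------------------------------------------------------------------------

EDGE_MODES = ("strong_negative", "significant", "strong_positive")


@dataclass
class IRCN:
    """Thresholded correlation network over spectral features.

    ``graph`` holds only features incident to at least one kept edge;
    ``total_features`` remembers the size of the full feature set before
    edge filtering (used by the pair-denominator ave_PCC convention).
    """

    graph: nx.Graph
    edge_mode: str
    rho_threshold: float
    alpha: float
    total_features: int
    features: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["rho"]) for a, b, d in self.graph.edges(data=True)]


def build_ircn(cm: CorrelationMatrix,
               mode: str = "strong_negative",
               rho_threshold: float = -0.6,
               alpha: float = 0.05) -> IRCN:
    """Threshold a correlation matrix into a network.

    strong_negative keeps pairs with rho <= rho_threshold and P < alpha
    (the metabolite-conversion criterion); significant keeps P < alpha;
    strong_positive keeps rho >= |rho_threshold| and P < alpha. NaN pairs
    are never kept. Nodes are the features incident to >= 1 kept edge.
    """
    if mode not in EDGE_MODES:
        raise IrcaError(f"unknown edge mode {mode!r}; choose from {EDGE_MODES}")
    if not 0.0 < alpha < 1.0:
        raise IrcaError("alpha must lie in (0, 1)")
    if mode == "strong_negative" and not -1.0 <= rho_threshold <= 0.0:
        raise IrcaError("rho_threshold must lie in [-1, 0] for strong_negative")

    rho, pval = cm.rho, cm.pval
    iu, ju = np.triu_indices(cm.n_features, k=1)
    r = rho[iu, ju]
    p = pval[iu, ju]
    with np.errstate(invalid="ignore"):
        if mode == "strong_negative":
            keep = (r <= rho_threshold) & (p < alpha)
        elif mode == "significant":
            keep = p < alpha
        else:
            keep = (r >= abs(rho_threshold)) & (p < alpha)
    keep &= np.isfinite(r) & np.isfinite(p)

    g = nx.Graph()
    feats = cm.features
    for i, j, rv in zip(iu[keep], ju[keep], r[keep]):
        g.add_edge(feats[i], feats[j], rho=float(rv),
                   pval=float(pval[i, j]))
    return IRCN(graph=g, edge_mode=mode, rho_threshold=rho_threshold,
                alpha=alpha, total_features=cm.n_features,
                features=list(feats))


def _wavenumber_key(label: str) -> tuple[int, float, str]:
    """Sort key: numeric labels ascending first, then names alphabetically."""
    try:
        return (0, float(label), "")
    except ValueError:
        return (1, 0.0, label)


def connected_modules(g: IRCN) -> list[set[str]]:
    """Connected components ('modules') sorted by size descending.

    Ties are broken by the smallest contained wavenumber so the order is
    deterministic.
    """
    comps = [set(c) for c in nx.connected_components(g.graph)]
    return sorted(
        comps,
        key=lambda c: (-len(c), min(_wavenumber_key(x) for x in c)),
    )


@dataclass(frozen=True)
class NetworkStats:
    """Topology summary of one IRCN.

    ave_pcc follows the pair-denominator convention: the sum of kept edge
    correlations divided by the number of all possible feature pairs
    C(total_features, 2) (switchable to a node denominator).
    """

    num_node: int
    num_edge: int
    num_module: int
    size_largest_module: int
    density: float
    ave_degree: float
    ave_pcc: float

    def as_dict(self) -> dict:
        return {
            "num_node": self.num_node, "num_edge": self.num_edge,
            "num_module": self.num_module,
            "size_largest_module": self.size_largest_module,
            "density": self.density, "ave_degree": self.ave_degree,
            "ave_pcc": self.ave_pcc,
        }


def network_stats(g: IRCN, ave_pcc_denominator: str = "pairs") -> NetworkStats:
    """Node/edge/module counts, density, average degree and average PCC.

    density = E / C(N, 2) over incident nodes N; ave_degree = 2E / N;
    an empty graph reports zeros throughout.
    """
    if ave_pcc_denominator not in ("pairs", "nodes"):
        raise IrcaError("ave_pcc_denominator must be 'pairs' or 'nodes'")
    n = g.graph.number_of_nodes()
    e = g.graph.number_of_edges()
    mods = connected_modules(g)
    rho_sum = float(sum(d["rho"] for _, _, d in g.graph.edges(data=True)))
    if ave_pcc_denominator == "pairs":
        den = g.total_features * (g.total_features - 1) / 2
    else:
        den = n
    return NetworkStats(
        num_node=n,
        num_edge=e,
        num_module=len(mods),
        size_largest_module=len(mods[0]) if mods else 0,
        density=(2.0 * e / (n * (n - 1))) if n > 1 else 0.0,
        ave_degree=(2.0 * e / n) if n > 0 else 0.0,
        ave_pcc=(rho_sum / den) if den > 0 else 0.0,
    )


def top_degree_peaks(g: IRCN, module: set[str] | None = None,
                     k: int | None = None) -> list[tuple[str, int]]:
    """Features of a module ranked by degree (descending).

    Ties are broken by ascending wavenumber. ``module`` defaults to the
    whole graph; ``k`` beyond the module size returns all members.
    """
    nodes = list(module) if module is not None else list(g.graph.nodes)
    for x in nodes:
        if x not in g.graph:
            raise IrcaError(f"node {x!r} not in network")
    ranked = sorted(
        ((x, g.graph.degree(x)) for x in nodes),
        key=lambda t: (-t[1], _wavenumber_key(t[0])),
    )
    return ranked[:k] if k is not None else ranked


@dataclass
class DeltaRhoMap:
    """Per-pair range of rho across a ramanome time series.

    delta[i, j] = max_t rho_t[i, j] - min_t rho_t[i, j]; argmax_t /
    argmin_t hold the time indices attaining the extremes.
    """

    features: list[str]
    delta: np.ndarray
    argmax_t: np.ndarray
    argmin_t: np.ndarray

    def pair(self, a: str, b: str) -> float:
        i, j = self.features.index(a), self.features.index(b)
        return float(self.delta[i, j])


def delta_rho(series: list[CorrelationMatrix]) -> DeltaRhoMap:
    """Range of each pairwise correlation over a time series of ramanomes.

    NaN entries at individual time points are skipped; pairs with fewer
    than 2 valid time points get a NaN delta.
    """
    if len(series) < 2:
        raise DegenerateInputError("delta_rho needs >= 2 correlation matrices")
    feats = series[0].features
    for cm in series[1:]:
        if cm.features != feats:
            raise IrcaError("correlation matrices have different feature sets")
    stack = np.stack([cm.rho for cm in series])  # T x F x F
    valid = np.isfinite(stack)
    n_valid = valid.sum(axis=0)
    if np.any(~valid):
        warnings.warn("NaN correlations skipped in delta_rho", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mx = np.nanmax(stack, axis=0)
        mn = np.nanmin(stack, axis=0)
        amx = np.nanargmax(np.where(valid, stack, -np.inf), axis=0)
        amn = np.nanargmin(np.where(valid, stack, np.inf), axis=0)
    delta = mx - mn
    delta[n_valid < 2] = np.nan
    return DeltaRhoMap(list(feats), delta, amx, amn)
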