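"""Signed co-occurrence network construction with RMT threshold selection.

The pipeline follows the molecular ecological network recipe: fill
"paired-valid" zeros in the relative-abundance table, compute pairwise
correlations, take absolute values as the similarity matrix, then scan
similarity thresholds from 0.30 to 1.00 (step 0.01).  At each threshold
the sub-threshold entries are zeroed, the eigenvalue spectrum of the
surviving matrix is unfolded, and the nearest-neighbour spacing
distribution (NNSD) is tested against the Poisson form e^{-d} (modular,
non-random network) versus the Wigner-Dyson/GOE form (pi d/2)e^{-pi d^2/4}
(random-matrix noise).  The chosen threshold is the smallest at which the
Poisson form fits and keeps fitting at every larger evaluable threshold.
A fixed comparative cutoff (0.88) is equally supported for building the
final network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.interpolate import PchipInterpolator
from scipy.stats import chi2 as chi2_dist
from scipy.stats import spearmanr

from .errors import EmptyNetworkError, NotEvaluableError, ValidationError

DEFAULT_GRID = np.round(np.arange(0.30, 1.0001, 0.01), 2)


@dataclass
class SimilarityMatrix:
    """Signed taxon x taxon correlation matrix; similarity = |correlation|."""

    corr: np.ndarray
    taxon_ids: list[str]
    method: str = "pearson"

    def __post_init__(self):
        c = np.asarray(self.corr, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValidationError("correlation matrix must be square")
        if c.shape[0] != len(self.taxon_ids):
            raise ValidationError("correlation matrix size does not match ids")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(c)) > 1 + 1e-8:
            raise ValidationError("correlations must lie in [-1, 1]")
        self.corr = c

    @property
    def similarity(self) -> np.ndarray:
        return np.abs(self.corr)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


@dataclass
class ThresholdRecord:
    threshold: float
    n_nodes: int
    n_eigenvalues: int
    chi2_poisson: float
    chi2_goe: float
    poisson_fits: bool
    evaluable: bool


@dataclass
class RmtScanResult:
    records: list[ThresholdRecord]
    chosen_threshold: float | None

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame([vars(r) for r in self.records])


@dataclass
class CoNetwork:
    """Undirected signed co-occurrence network (isolated taxa dropped)."""

    graph: nx.Graph
    cutoff: float
    method: str = "pearson"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()


def fill_missing(relabund: np.ndarray, fill: float = 0.01,
                 majority_rule: bool = True) -> np.ndarray:
    """Replace zeros of majority-nonzero taxa with a small constant.

    ``fill`` is given on the percentage relative-abundance scale (0.01
    means 0.01% = 1e-4 as a fraction), matching percent-scaled pipeline
    tables, and is applied only to taxa that are nonzero in more than
    half of the samples unless ``majority_rule`` is disabled.
    """
    x = np.array(relabund, dtype=float)
    value = fill / 100.0
    if value == 0:
        return x
    if majority_rule:
        cols = (x > 0).mean(axis=0) > 0.5
    else:
        cols = np.ones(x.shape[1], dtype=bool)
    zeros = (x == 0) & cols[None, :]
    x[zeros] = value
    return x


def correlation_matrix(mat: np.ndarray, taxon_ids: list[str],
                       method: str = "pearson") -> SimilarityMatrix:
    """Pairwise Pearson or Spearman correlations between taxa (columns).

    Constant columns are removed with a warning; fewer than four samples
    is an error (a correlation from 3 points is meaningless here).
    """
    x = np.asarray(mat, dtype=float)
    if x.shape[0] < 4:
        raise ValidationError("correlation needs at least 4 samples")
    if x.shape[1] != len(taxon_ids):
        raise ValidationError("column count does not match taxon ids")
    keep = x.std(axis=0) > 0
    if not np.all(keep):
        dropped = [t for t, k in zip(taxon_ids, keep) if not k]
        warnings.warn(f"removing {len(dropped)} constant taxa before "
                      f"correlation: {dropped[:5]}...")
        x = x[:, keep]
        taxon_ids = [t for t, k in zip(taxon_ids, keep) if k]
    if x.shape[1] < 2:
        raise ValidationError("need at least two non-constant taxa")
    if method == "pearson":
        corr = np.corrcoef(x, rowvar=False)
    elif method == "spearman":
        corr = spearmanr(x).statistic
        if np.ndim(corr) == 0:  # spearmanr collapses the 2-taxon case
            corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SimilarityMatrix(corr, list(taxon_ids), method)


def unfold_spectrum(eigenvalues, degeneracy_tol: float = 1e-8,
                    min_distinct: int = 20) -> np.ndarray:
    """Unfold a spectrum so nearest-neighbour spacings have unit mean.

    Degenerate eigenvalues (within ``degeneracy_tol``) are collapsed; the
    cumulative spectral function is smoothed by a monotone (PCHIP) cubic
    through ~n/10 knots and the unfolded levels are e_i = n * G(lambda_i).
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    distinct = [lam[0]]
    for v in lam[1:]:
        if v - distinct[-1] > degeneracy_tol:
            distinct.append(v)
    lam = np.asarray(distinct)
    n = len(lam)
    if n < min_distinct:
        raise NotEvaluableError(
            f"only {n} distinct eigenvalues (< {min_distinct})")
    n_knots = max(5, int(np.ceil(n / 10)))
    knot_idx = np.unique(np.round(np.linspace(0, n - 1, n_knots)).astype(int))
    g = PchipInterpolator(lam[knot_idx], (knot_idx + 1.0) / n)
    unfolded = n * g(lam)
    return np.diff(unfolded)


def _pooled_chi2(observed: np.ndarray, expected: np.ndarray,
                 min_expected: float = 1.0) -> tuple[float, int]:
    """Chi-square GOF with left-to-right pooling of thin expected bins."""
    obs_p, exp_p = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_p.append(o_acc)
            exp_p.append(e_acc)
            o_acc = e_acc = 0.0
    if obs_p:
        obs_p[-1] += o_acc
        exp_p[-1] += e_acc
    else:  # everything thinner than min_expected
        obs_p, exp_p = [o_acc], [max(e_acc, min_expected)]
    obs_a, exp_a = np.asarray(obs_p), np.asarray(exp_p)
    stat = float(((obs_a - exp_a) ** 2 / exp_a).sum())
    return stat, max(len(obs_a) - 1, 1)


def nnsd_test(spacings, n_bins: int = 20,
              alpha: float = 0.001) -> tuple[float, float, bool]:
    """Compare a spacing histogram against Poisson and GOE NNSD forms.

    Returns (chi2_poisson, chi2_goe, poisson_fits) where poisson_fits
    requires both chi2_poisson < chi2_goe and chi2_poisson below the
    ``alpha``-level critical value for its pooled degrees of freedom.
    """
    s = np.asarray(spacings, dtype=float)
    if len(s) < 20:
        raise ValidationError("need at least 20 spacings")
    top = s.max()
    if top <= 0:
        raise NotEvaluableError("all spacings are zero")
    observed, edges = np.histogram(s, bins=n_bins, range=(0.0, top))
    if (observed > 0).sum() <= 1:
        raise NotEvaluableError("degenerate spacing histogram")
    n = len(s)
    # closed tail bin [max, inf) so each model's expected mass sums to n
    cdf_p = 1.0 - np.exp(-edges)
    cdf_g = 1.0 - np.exp(-np.pi * edges ** 2 / 4.0)
    exp_p = n * np.append(np.diff(cdf_p), 1.0 - cdf_p[-1])
    exp_g = n * np.append(np.diff(cdf_g), 1.0 - cdf_g[-1])
    obs = np.append(observed, 0.0)
    chi2_p, df_p = _pooled_chi2(obs, exp_p)
    chi2_g, _ = _pooled_chi2(obs, exp_g)
    critical = chi2_dist.isf(alpha, df_p)
    fits = bool(chi2_p < chi2_g and chi2_p < critical)
    return chi2_p, chi2_g, fits


def _threshold_submatrix(similarity: np.ndarray, threshold: float) -> np.ndarray:
    a = np.where(similarity >= threshold, similarity, 0.0)
    np.fill_diagonal(a, 1.0)
    keep = (np.count_nonzero(a, axis=1) > 1)
    return a[np.ix_(keep, keep)]


def rmt_threshold_scan(sim: SimilarityMatrix, grid=None,
                       min_distinct: int = 20) -> RmtScanResult:
    """Scan similarity thresholds and pick the RMT transition point.

    The chosen threshold is the smallest grid value where the NNSD fits
    the Poisson form and continues to fit at every larger evaluable
    threshold (the GOE-to-Poisson transition is one-directional).
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    s = sim.similarity
    records: list[ThresholdRecord] = []
    for t in grid:
        sub = _threshold_submatrix(s, t)
        n_nodes = sub.shape[0]
        rec = ThresholdRecord(float(t), n_nodes, 0, np.nan, np.nan,
                              poisson_fits=False, evaluable=False)
        if n_nodes >= min_distinct:
            eig = np.linalg.eigvalsh(sub)
            rec.n_eigenvalues = len(eig)
            try:
                spacings = unfold_spectrum(eig, min_distinct=min_distinct)
                chi_p, chi_g, fits = nnsd_test(spacings)
            except (NotEvaluableError, ValidationError):
                pass
            else:
                rec.chi2_poisson, rec.chi2_goe = chi_p, chi_g
                rec.poisson_fits = fits
                rec.evaluable = True
        records.append(rec)
    evaluable = [r for r in records if r.evaluable]
    if not evaluable:
        raise ValidationError(
            "no threshold was evaluable; the similarity matrix is too small "
            "for spectral unfolding — provide more taxa")
    chosen = None
    for r in records:
        if not r.evaluable or not r.poisson_fits:
            continue
        later = [q for q in records if q.threshold > r.threshold and q.evaluable]
        if all(q.poisson_fits for q in later):
            chosen = r.threshold
            break
    return RmtScanResult(records, chosen)


def build_network(sim: SimilarityMatrix, cutoff: float,
                  partition=None, taxonomy: dict[str, str] | None = None,
                  method: str | None = None) -> CoNetwork:
    """Build the signed network with edges where similarity >= cutoff.

    Edge signs come from the correlation sign; isolated taxa are dropped.
    Node attributes carry the abundance class (from ``partition``) and the
    domain tag (kingdom parsed from ``taxonomy``) when available.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValidationError("cutoff must lie in [0, 1]")
    s = sim.similarity
    iu = np.triu_indices(sim.n_taxa, k=1)
    hits = s[iu] >= cutoff
    if not hits.any():
        raise EmptyNetworkError(
            f"no edge reaches cutoff {cutoff}; the largest off-diagonal "
            f"similarity is {s[iu].max() if len(iu[0]) else 0:.3f} — lower "
            "the cutoff or supply more correlated taxa")
    classes = {}
    if partition is not None:
        classes = dict(zip(partition.taxon_ids, partition.labels))
    g = nx.Graph()
    for i, j in zip(iu[0][hits], iu[1][hits]):
        r = sim.corr[i, j]
        g.add_edge(sim.taxon_ids[i], sim.taxon_ids[j],
                   correlation=float(r), sign="-" if r < 0 else "+")
    for node in g.nodes:
        if node in classes:
            g.nodes[node]["abundance_class"] = str(classes[node])
        if taxonomy and node in taxonomy:
            from .io_tables import parse_taxonomy_string
            g.nodes[node]["domain"] = parse_taxonomy_string(
                taxonomy[node])["kingdom"].lower() or "unknown"
    return CoNetwork(g, float(cutoff), method or sim.method)


def network_from_table(table, taxa: list[str], cutoff: float,
                       partition=None, method: str = "pearson",
                       fill: float = 0.01) -> CoNetwork:
    """Convenience route: sub-table -> fill -> correlation -> network."""
    from .partition import relative_abundance
    pos = {t: i for i, t in enumerate(table.taxon_ids)}
    rel = relative_abundance(table)[:, [pos[t] for t in taxa]]
    filled = fill_missing(rel, fill=fill)
    sim = correlation_matrix(filled, taxa, method=method)
    return build_network(sim, cutoff, partition=partition,
                         taxonomy=table.taxonomy, method=method)
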