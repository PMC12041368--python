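"""Gene x mutational-signature regression scan with a permutation null.

For each candidate susceptibility gene and each COSMIC-style signature the
per-sample activity is regressed on the gene's expression by ordinary
least squares; the slope's two-sided t-test p-value is the association
statistic.  Significant pairs are counted per signature at a nominal
p < alpha with no multiplicity correction (BH adjustment is available
behind a flag).

The suitability of a susceptibility gene list is tested by permutation:
equally sized gene sets are drawn uniformly without replacement from all
expressed genes, the scan is re-run for each draw, and the permutation
p-value is N / n_iter where N counts draws whose total number of
significant pairs STRICTLY exceeds the observed total.

Signatures are mapped to proposed etiology groups (mismatch repair
deficiency, homologous recombination deficiency, age-related mutagenesis,
platinum chemotherapy treatment, environmental factors, APOBEC
mutagenesis) for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: Proposed etiology of signatures recurrently active in ovarian tumors,
#: following the COSMIC catalog's assignments.
DEFAULT_ETIOLOGY: dict[str, str] = {
    "SBS26": "mismatch repair deficiency",
    "DBS7": "mismatch repair deficiency",
    "SBS3": "homologous recombination deficiency",
    "ID1": "homologous recombination deficiency",
    "ID2": "homologous recombination deficiency",
    "ID6": "homologous recombination deficiency",
    "ID8": "homologous recombination deficiency",
    "SBS40": "age-related mutagenesis",
    "SBS5": "age-related mutagenesis",
    "SBS1": "age-related mutagenesis",
    "ID4": "age-related mutagenesis",
    "ID5": "age-related mutagenesis",
    "DBS4": "age-related mutagenesis",
    "SBS35": "platinum chemotherapy treatment",
    "DBS5": "platinum chemotherapy treatment",
    "SBS18": "environmental factors",
    "DBS2": "environmental factors",
    "SBS2": "APOBEC mutagenesis",
    "SBS13": "APOBEC mutagenesis",
    "DBS11": "APOBEC mutagenesis",
}


@dataclass(frozen=True)
class AssociationResult:
    """OLS outcome for one (gene, signature) pair."""

    gene: str
    signature: str
    slope: float
    intercept: float
    p_value: float
    n_samples: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the random-gene-list permutation test."""

    gene_list_name: str
    n_iter: int
    observed: int
    n_exceed: int
    p_value: float
    null_counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.null_counts) != self.n_iter:
            raise ValueError("null_counts length must equal n_iter")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value out of [0,1]")


# ---------------------------------------------------------------------------
# Single-pair fit
# ---------------------------------------------------------------------------

def fit_pair(expr: np.ndarray, activity: np.ndarray, gene: str = "gene",
             signature: str = "signature") -> AssociationResult:
    """OLS of activity on expression for one pair.

    Samples with a missing value in either vector are dropped pairwise.
    Zero expression variance yields a degenerate result (slope 0, p 1);
    a constant activity vector yields slope 0, p 1.
    """
    x = np.asarray(expr, dtype=float)
    y = np.asarray(activity, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expr and activity must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete sample pairs, got {n}")
    if np.ptp(x) == 0:
        return AssociationResult(gene, signature, 0.0, float(np.mean(y)),
                                 1.0, n, degenerate=True)
    if np.ptp(y) == 0:
        return AssociationResult(gene, signature, 0.0, float(y[0]), 1.0, n)
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    p = min(max(p, 0.0), 1.0)
    return AssociationResult(gene, signature, float(res.slope),
                             float(res.intercept), p, n)


def _ols_matrix(X: np.ndarray, Y: np.ndarray):
    """Vectorized simple-OLS slope/intercept/two-sided p for all pairs.

    X is n x g (predictors), Y is n x s (responses).  Returns g x s arrays.
    Equivalent to running :func:`fit_pair` on every column pair; pairs with
    a zero-variance predictor or response get slope 0 and p 1.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = (Xc ** 2).sum(axis=0)          # g
    syy = (Yc ** 2).sum(axis=0)          # s
    sxy = Xc.T @ Yc                      # g x s
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx[:, None]
        r2 = sxy ** 2 / (sxx[:, None] * syy[None, :])
        r2 = np.clip(r2, 0.0, 1.0)
        # residual variance of y given x; t-statistic of the slope
        tstat = np.sqrt(np.clip(r2 * (n - 2) / (1 - r2), 0, np.inf))
        p = 2 * stats.t.sf(tstat, df=n - 2)
    p = np.where(r2 >= 1.0, 0.0, p)
    bad = (sxx[:, None] == 0) | (syy[None, :] == 0)
    slope = np.where(bad, 0.0, slope)
    p = np.where(bad, 1.0, p)
    intercept = Y.mean(axis=0)[None, :] - slope * X.mean(axis=0)[:, None]
    return slope, intercept, p


def log2_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1), the default expression transform before fitting."""
    return np.log2(expr + 1.0)


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def scan(
    expr_matrix: pd.DataFrame,
    activity_matrix: pd.DataFrame,
    gene_list: list[str],
    alpha: float = 0.05,
    log_transform: bool = True,
    list_name: str = "gene_list",
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regress every signature on every listed gene; count significant pairs.

    Samples are intersected by id between the two matrices; genes in the
    list but absent from the expression matrix are logged and skipped.
    Returns (results, counts): per-pair results and a per-signature table
    of the number of listed genes significant at nominal p < alpha (or
    BH q < alpha when ``bh_correct``).
    """
    samples = expr_matrix.index.intersection(activity_matrix.index)
    if len(samples) == 0:
        raise ValueError("no samples shared between expression and activity")
    present = [g for g in gene_list if g in expr_matrix.columns]
    missing = [g for g in gene_list if g not in expr_matrix.columns]
    if missing:
        logger.info("scan: %d gene(s) absent from expression matrix: %s",
                    len(missing), ", ".join(missing[:10]))
    expr = expr_matrix.loc[samples, present]
    if log_transform:
        expr = log2_transform(expr)
    act = activity_matrix.loc[samples]
    X = expr.to_numpy(dtype=float)
    Y = act.to_numpy(dtype=float)
    slope, intercept, p = _ols_matrix(X, Y)
    genes = np.repeat(present, act.shape[1])
    sigs = np.tile(act.columns.to_numpy(), len(present))
    results = pd.DataFrame({
        "gene": genes,
        "signature": sigs,
        "slope": slope.ravel(),
        "intercept": intercept.ravel(),
        "p_value": p.ravel(),
        "n_samples": len(samples),
    })
    pcol = results["p_value"]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        results["q_value"] = multipletests(pcol, method="fdr_bh")[1]
        results["significant"] = results["q_value"] < alpha
    else:
        results["significant"] = pcol < alpha
    counts = (
        results.groupby("signature", sort=False)["significant"]
        .sum().astype(int).rename("n_significant").reset_index()
    )
    counts.insert(1, "gene_list_name", list_name)
    return results, counts


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    expr_matrix: pd.DataFrame,
    activity_matrix: pd.DataFrame,
    gene_list: list[str],
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    log_transform: bool = True,
    list_name: str = "gene_list",
    plus_one: bool = False,
) -> PermutationResult:
    """Random-gene-list null for the total count of significant pairs.

    Each iteration draws ``len(gene_list)`` genes uniformly without
    replacement from ALL expressed genes (including the candidates
    themselves), re-runs the scan, and records the total number of
    significant (gene, signature) pairs.  The p-value is N / n_iter with a
    STRICT "exceeds" counter; ``plus_one`` switches to the
    (N + 1) / (n_iter + 1) small-sample form.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    samples = expr_matrix.index.intersection(activity_matrix.index)
    if len(samples) == 0:
        raise ValueError("no samples shared between expression and activity")
    present = [g for g in gene_list if g in expr_matrix.columns]
    k = len(present)
    all_genes = expr_matrix.columns
    if len(all_genes) <= k:
        raise ValueError("expression matrix must contain more genes than "
                         "the candidate list")
    expr = expr_matrix.loc[samples]
    if log_transform:
        expr = log2_transform(expr)
    act = activity_matrix.loc[samples]
    # significance of every (gene, signature) pair is list-independent,
    # so compute it once and resample rows
    _, _, p = _ols_matrix(expr.to_numpy(dtype=float),
                          act.to_numpy(dtype=float))
    sig_per_gene = (p < alpha).sum(axis=1)  # length = all genes
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    observed = int(sig_per_gene[[gene_pos[g] for g in present]].sum())
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_iter, dtype=int)
    n_genes = len(all_genes)
    for it in range(n_iter):
        idx = rng.choice(n_genes, size=k, replace=False)
        null_counts[it] = sig_per_gene[idx].sum()
    n_exceed = int((null_counts > observed).sum())
    if plus_one:
        p_value = (n_exceed + 1) / (n_iter + 1)
    else:
        p_value = n_exceed / n_iter
    return PermutationResult(list_name, n_iter, observed, n_exceed,
                             float(p_value), null_counts)


def map_etiology(signature_id: str,
                 etiology_map: dict[str, str] | None = None) -> str:
    """Proposed etiology group for a signature; unknown → 'unassigned'."""
    mapping = DEFAULT_ETIOLOGY if etiology_map is None else etiology_map
    return mapping.get(signature_id, UNASSIGNED)
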