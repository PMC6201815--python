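"""Label-free IP-MS enrichment versus mock.

Pipeline: log2 transform, per-sample imputation of missing values from a
downshifted normal (shift 1.8 sd, width 0.3 sd of the observed sample
distribution), per-sample median subtraction, Welch t-test per protein
against mock, Benjamini-Hochberg FDR (permutation FDR available), and an
enriched call at q <= 0.05 with positive log2 fold change.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_FDR = 0.05
DEFAULT_IMPUTE_SHIFT = 1.8  # sd units below the observed mean
DEFAULT_IMPUTE_WIDTH = 0.3  # sd units

FDR_METHODS = ("bh", "permutation")


def read_intensity_matrix(path: str | Path) -> pd.DataFrame:
    """TSV with a protein-id first column; empty cells are missing values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.dropna().values <= 0).any():
        raise ValueError(f"{path}: intensities must be positive where present")
    return df.astype(float)


def preprocess(
    matrix: pd.DataFrame,
    shift: float = DEFAULT_IMPUTE_SHIFT,
    width: float = DEFAULT_IMPUTE_WIDTH,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """log2 transform, impute missing values, median-center each sample.

    Imputed values for a sample are drawn from
    Normal(mean - shift*sd, width*sd) of that sample's observed log2
    distribution, emulating missing-not-at-random dropouts near the
    detection limit.  After centering every sample median is exactly 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    logm = np.log2(matrix.astype(float))
    out = logm.copy()
    for col in out.columns:
        obs = out[col].dropna()
        if len(obs) < 2:
            raise ValueError(f"sample {col}: fewer than 2 observed values")
        missing = out[col].isna()
        if missing.any():
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
            draws = rng.normal(mu - shift * sd, width * sd, int(missing.sum()))
            out.loc[missing, col] = draws
        out[col] = out[col] - out[col].median()
    return out


@dataclass
class EnrichmentResult:
    protein: str
    log2_fold_change: float
    p: float
    q: float
    enriched: bool


def _ttest_p(ip: np.ndarray, mock: np.ndarray, equal_var: bool = False) -> np.ndarray:
    p = stats.ttest_ind(ip, mock, axis=1, equal_var=equal_var).pvalue
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: p = 1 when means agree, ~0 otherwise
    var0 = (ip.var(axis=1) == 0) & (mock.var(axis=1) == 0)
    same = np.isclose(ip.mean(axis=1), mock.mean(axis=1))
    p[var0 & same] = 1.0
    p[var0 & ~same] = np.finfo(float).tiny
    p[np.isnan(p)] = 1.0
    return p


def differential_enrichment(
    matrix: pd.DataFrame,
    ip_samples: Sequence[str],
    mock_samples: Sequence[str],
    fdr: float = DEFAULT_FDR,
    method: str = "bh",
    welch: bool = True,
    max_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-protein t-test of IP versus mock on a preprocessed matrix.

    Returns a DataFrame with columns protein, log2_fold_change, p, q,
    enriched, sorted by q.  ``method`` selects Benjamini-Hochberg (default)
    or permutation-based FDR estimation of per-protein p-values; ``welch``
    toggles between unequal-variance (default) and pooled-variance tests.
    """
    if method not in FDR_METHODS:
        raise ValueError(f"method must be one of {FDR_METHODS}")
    if len(ip_samples) < 2 or len(mock_samples) < 2:
        raise ValueError("need >= 2 replicates per tested group")
    ip = matrix[list(ip_samples)].to_numpy(dtype=float)
    mock = matrix[list(mock_samples)].to_numpy(dtype=float)
    log2fc = ip.mean(axis=1) - mock.mean(axis=1)

    if method == "bh":
        p = _ttest_p(ip, mock, equal_var=not welch)
    else:
        p = _permutation_p(ip, mock, max_permutations=max_permutations, seed=seed)
    q = multipletests(p, method="fdr_bh")[1]
    enriched = (q <= fdr) & (log2fc > 0)
    return pd.DataFrame(
        dict(
            protein=matrix.index,
            log2_fold_change=log2fc,
            p=p,
            q=q,
            enriched=enriched,
        )
    ).sort_values("q", kind="stable", ignore_index=True)


def _t_stats(ip: np.ndarray, mock: np.ndarray) -> np.ndarray:
    n1, n2 = ip.shape[1], mock.shape[1]
    v1 = ip.var(axis=1, ddof=1) / n1
    v2 = mock.var(axis=1, ddof=1) / n2
    denom = np.sqrt(v1 + v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ip.mean(axis=1) - mock.mean(axis=1)) / denom
    t[np.isnan(t)] = 0.0
    return t


def _permutation_p(
    ip: np.ndarray,
    mock: np.ndarray,
    max_permutations: int,
    seed: int,
) -> np.ndarray:
    """Pooled-null permutation p-values for |t| (label permutations)."""
    data = np.hstack([ip, mock])
    n1 = ip.shape[1]
    n = data.shape[1]
    identity = tuple(range(n1))
    combos = [
        c for c in itertools.combinations(range(n), n1)
        if c != identity and c != tuple(range(n1, n))
    ]
    rng = np.random.default_rng(seed)
    if len(combos) > max_permutations:
        combos = [combos[i] for i in rng.choice(len(combos), max_permutations, replace=False)]
    obs = np.abs(_t_stats(ip, mock))
    null = []
    for combo in combos:
        idx1 = list(combo)
        idx2 = [i for i in range(n) if i not in combo]
        null.append(np.abs(_t_stats(data[:, idx1], data[:, idx2])))
    pooled = np.sort(np.concatenate(null))
    # p = fraction of pooled null statistics >= observed
    ranks = np.searchsorted(pooled, obs, side="left")
    return (len(pooled) - ranks + 1) / (len(pooled) + 1)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    out = results[["protein", "log2_fold_change", "p", "enriched"]].copy()
    with np.errstate(divide="ignore"):
        out["minus_log10_p"] = -np.log10(out.pop("p"))
    return out


def fold_enrichment_scatter(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    label_a: str = "a",
    label_b: str = "b",
) -> pd.DataFrame:
    """Join two enrichment tables on protein for pairwise fold-change scatter."""
    a = results_a.set_index("protein")["log2_fold_change"].rename(f"log2fc_{label_a}")
    b = results_b.set_index("protein")["log2_fold_change"].rename(f"log2fc_{label_b}")
    return pd.concat([a, b], axis=1, join="inner").reset_index()
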