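"""Tag-count digital expression between EST libraries.

For one gene with counts :math:`x_j` in libraries of sizes :math:`N_j`,
the log-likelihood-ratio statistic of library-specific Poisson rates
against a single pooled rate :math:`f = \\sum_j x_j / \\sum_j N_j` is

.. math::  R = \\sum_j x_j \\log \\frac{x_j}{N_j f},

with :math:`0 \\log 0 = 0`.  R is 0 iff the per-library proportions
coincide and grows with evidence for differential expression.  Raw
p-values come from the asymptotic :math:`\\chi^2_{m-1}` tail of
:math:`2R` (a Monte Carlo permutation of the pooled counts is also
available), and are converted to q-values (Benjamini-Hochberg, or the
Storey variant with a fixed lambda).  A gene is called differentially
expressed when the pseudocounted normalized fold change exceeds
``fold_threshold`` and q falls below ``q_threshold``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mapping import SplicedAlignment

LIBRARIES = ("G", "H")


def count_tags(
    assignments: Iterable[SplicedAlignment | tuple[str, str, str]],
    libraries: Sequence[str] = LIBRARIES,
) -> pd.DataFrame:
    """Per-gene tag counts per library.

    Accepts assigned :class:`SplicedAlignment` objects or plain
    ``(est_id, library, gene_id)`` triples.  Library sizes (the totals
    of assigned reads) are stored in ``df.attrs["library_sizes"]``;
    unassigned reads are excluded by construction.
    """
    tallies: dict[str, dict[str, int]] = {}
    for a in assignments:
        if isinstance(a, SplicedAlignment):
            lib, gid = a.library, a.gene_id
        else:
            _, lib, gid = a
        if lib not in libraries:
            raise ValueError(f"unknown library tag {lib!r}")
        row = tallies.setdefault(gid, dict.fromkeys(libraries, 0))
        row[lib] += 1
    df = pd.DataFrame.from_dict(tallies, orient="index").fillna(0).astype(int)
    df = df.reindex(columns=list(libraries), fill_value=0).sort_index()
    df.attrs["library_sizes"] = {lib: int(df[lib].sum()) for lib in libraries}
    return df


def r_statistic(x: Sequence[float], N: Sequence[float]) -> float:
    """Stekel-style log-likelihood-ratio statistic for one gene.

    Requires all library sizes positive and at least one nonzero count.
    """
    x = np.asarray(x, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("library sizes must be positive")
    total = x.sum()
    if total <= 0:
        raise ValueError("R is undefined for all-zero counts")
    f = total / N.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / (N * f)), 0.0)
    return float(max(terms.sum(), 0.0))


def r_pvalue(
    R: float,
    m: int = 2,
    method: str = "chisq",
    *,
    x_total: int | None = None,
    N: Sequence[float] | None = None,
    reps: int = 2000,
    seed: int | None = None,
) -> float:
    """Raw p-value for an observed R.

    ``chisq`` uses the upper tail of chi-square with m-1 df at 2R.
    ``montecarlo`` resamples the pooled total over libraries in
    proportion to their sizes and applies the (r+1)/(n+1) correction;
    it needs ``x_total`` and ``N``.
    """
    if method == "chisq":
        return float(stats.chi2.sf(2.0 * R, df=m - 1))
    if method == "montecarlo":
        if x_total is None or N is None:
            raise ValueError("montecarlo needs x_total and N")
        rng = np.random.default_rng(seed)
        N = np.asarray(N, dtype=float)
        p = N / N.sum()
        draws = rng.multinomial(int(x_total), p, size=reps)
        f = x_total / N.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(np.where(draws > 0, draws, 1.0) / (N * f))
        null_R = np.where(draws > 0, draws * logs, 0.0).sum(axis=1)
        r = int((null_R >= R - 1e-12).sum())
        return (r + 1) / (reps + 1)
    raise ValueError(f"unknown p-value method {method!r}")


def qvalues(p: Sequence[float], method: str = "BH", lam: float = 0.5) -> np.ndarray:
    """Convert raw p-values to q-values.

    ``BH`` is the Benjamini-Hochberg step-up; ``storey`` scales BH by
    the estimated null proportion pi0 = #(p > lambda) / ((1-lambda) m),
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    q = multipletests(p, method="fdr_bh")[1]
    if method == "BH":
        return q
    if method == "storey":
        pi0 = min(1.0, float((p > lam).sum()) / ((1.0 - lam) * p.size))
        return np.minimum(q * pi0, 1.0)
    raise ValueError(f"unknown q-value method {method!r}")


def call_de(
    counts: pd.DataFrame,
    fold_threshold: float = 2.0,
    q_threshold: float = 0.05,
    p_method: str = "chisq",
    q_method: str = "BH",
    library_sizes: dict[str, int] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Differential-expression table for a two-library count matrix.

    Fold change uses +1 pseudocounts on raw counts before normalization:
    ``((x1+1)/N1) / ((x2+1)/N2)`` oriented so fold >= 1, with
    ``direction`` naming the higher library.  Genes with zero counts in
    both libraries are excluded.  DE requires fold > fold_threshold and
    q < q_threshold.
    """
    libs = list(counts.columns)
    if len(libs) != 2:
        raise ValueError("call_de expects exactly two libraries")
    sizes = library_sizes or counts.attrs.get("library_sizes") or {
        lib: int(counts[lib].sum()) for lib in libs
    }
    N = np.array([sizes[libs[0]], sizes[libs[1]]], dtype=float)
    df = counts.loc[counts.sum(axis=1) > 0].copy()
    x = df[libs].to_numpy(dtype=float)

    R = np.array([r_statistic(row, N) for row in x])
    if p_method == "chisq":
        p = stats.chi2.sf(2.0 * R, df=1)
    else:
        p = np.array(
            [
                r_pvalue(r, 2, "montecarlo", x_total=int(row.sum()), N=N, seed=seed)
                for r, row in zip(R, x)
            ]
        )
    q = qvalues(p, method=q_method)

    rate = (x + 1.0) / N
    fold = np.where(rate[:, 0] >= rate[:, 1], rate[:, 0] / rate[:, 1], rate[:, 1] / rate[:, 0])
    direction = np.where(rate[:, 0] >= rate[:, 1], libs[0], libs[1])
    de = (fold > fold_threshold) & (q < q_threshold)

    out = df.copy()
    out["N_" + libs[0]], out["N_" + libs[1]] = int(N[0]), int(N[1])
    out["pooled_rate"] = x.sum(axis=1) / N.sum()
    out["R"] = R
    out["p"] = p
    out["q"] = q
    out["fold"] = fold
    out["direction"] = direction
    out["de"] = de
    return out
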