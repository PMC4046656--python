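"""Two-sample differential expression without replicates.

The model is the negative binomial Y_i ~ NB(mean = M_i * p_i, dispersion
= phi) with variance mu + phi * mu^2, where M_i is the library size and
p_i the relative abundance of the gene in sample i.  With one library
per condition the dispersion is not estimable from the data, so it is a
fixed, documented parameter (default 0.1); phi = 0 recovers the Poisson
model exactly.

The test is a conditional exact test: given the two-sample total
n = y1 + y2 and the pooled abundance p = n / (M1 + M2), the conditional
distribution of Y1 is obtained by normalizing f(k; M1*p, phi) *
f(n-k; M2*p, phi) over k = 0..n.  The two-sided p-value sums the
conditional probabilities of every outcome no more likely than the
observed one (minimum-likelihood rule).  At phi = 0 this is exactly the
binomial(n, M1/(M1+M2)) two-sided exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson
from statsmodels.stats.multitest import multipletests

from .quantification import ExpressionRecord

__all__ = ["NBModelParams", "DEResult", "nb_exact_test", "log_fold_change", "run_de"]

#: relative tolerance when deciding which outcomes tie with the observed
#: probability; guards the minimum-likelihood sum against round-off.
_TIE_REL = 1e-12


@dataclass(frozen=True)
class NBModelParams:
    """Fixed test parameters: common dispersion, level, logFC pseudocount."""

    phi: float = 0.1
    alpha: float = 0.01
    pseudocount: float = 0.5
    two_sided_rule: str = "minlike"  # or "doubling"

    def __post_init__(self):
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.two_sided_rule not in ("minlike", "doubling"):
            raise ValueError(f"unknown two-sided rule {self.two_sided_rule!r}")


@dataclass(frozen=True)
class DEResult:
    unigene_id: str
    y: tuple[int, int]
    logfc: float
    pvalue: float
    significant: bool
    padj: float = float("nan")


def _conditional_log_pmf(n: int, m1: float, m2: float, phi: float) -> np.ndarray:
    """log P(Y1 = k | Y1 + Y2 = n) for k = 0..n under the NB model."""
    phat = n / (m1 + m2)
    mu1, mu2 = m1 * phat, m2 * phat
    k = np.arange(n + 1)
    if phi == 0.0:
        logp = poisson.logpmf(k, mu1) + poisson.logpmf(n - k, mu2)
    else:
        r = 1.0 / phi
        logp = nbinom.logpmf(k, r, r / (r + mu1)) + nbinom.logpmf(n - k, r, r / (r + mu2))
    return logp - logsumexp(logp)


def nb_exact_test(y1: int, y2: int, m1: float, m2: float, phi: float = 0.1,
                  two_sided_rule: str = "minlike") -> float:
    """Conditional two-sided exact p-value for counts (y1, y2).

    Parameters
    ----------
    y1, y2
        Observed counts in the two samples.
    m1, m2
        Library sizes (total reads) of the two samples.
    phi
        Common NB dispersion; 0 gives the Poisson/binomial reduction.
    two_sided_rule
        ``"minlike"`` (default) sums all conditional outcomes with
        probability <= that of the observed count; ``"doubling"``
        doubles the smaller conditional tail.
    """
    if y1 < 0 or y2 < 0 or int(y1) != y1 or int(y2) != y2:
        raise ValueError("counts must be non-negative integers")
    if m1 < 1 or m2 < 1:
        raise ValueError("library sizes must be >= 1")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    y1, y2 = int(y1), int(y2)
    n = y1 + y2
    if n == 0:
        return 1.0
    logp = _conditional_log_pmf(n, m1, m2, phi)
    if two_sided_rule == "doubling":
        lower = logsumexp(logp[: y1 + 1])
        upper = logsumexp(logp[y1:])
        p = 2.0 * np.exp(min(lower, upper))
    elif two_sided_rule == "minlike":
        cutoff = logp[y1] + np.log1p(_TIE_REL)
        p = np.exp(logsumexp(logp[logp <= cutoff]))
    else:
        raise ValueError(f"unknown two-sided rule {two_sided_rule!r}")
    return float(min(1.0, p))


def log_fold_change(y1: int, y2: int, m1: float, m2: float, pseudocount: float = 0.5) -> float:
    """Base-2 log fold change of library-size-normalized counts.

    A pseudocount keeps the value finite for genes expressed exclusively
    in one sample, so they plot at a finite x in a volcano display.
    """
    if y1 < 0 or y2 < 0:
        raise ValueError("counts must be non-negative")
    if m1 < 1 or m2 < 1:
        raise ValueError("library sizes must be >= 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return float(np.log2(((y1 + pseudocount) / m1) / ((y2 + pseudocount) / m2)))


def run_de(expression_table: list[ExpressionRecord], params: NBModelParams | None = None) -> list[DEResult]:
    """Test every unigene; significance is raw p < alpha (no correction).

    A Benjamini-Hochberg adjusted column is reported for reference but
    does not drive the significance flag.
    """
    params = params or NBModelParams()
    if not expression_table:
        return []
    results = []
    for rec in expression_table:
        s1, s2 = rec.sample_ids
        y1, y2 = rec.raw_count[s1], rec.raw_count[s2]
        m1, m2 = rec.library_size[s1], rec.library_size[s2]
        p = nb_exact_test(y1, y2, m1, m2, params.phi, params.two_sided_rule)
        lfc = log_fold_change(y1, y2, m1, m2, params.pseudocount)
        results.append(DEResult(rec.unigene_id, (y1, y2), lfc, p, p < params.alpha))
    padj = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
    return [
        DEResult(r.unigene_id, r.y, r.logfc, r.pvalue, r.significant, float(q))
        for r, q in zip(results, padj)
    ]


def de_results_frame(results: list[DEResult], sample_ids: tuple[str, str]) -> pd.DataFrame:
    s1, s2 = sample_ids
    return pd.DataFrame(
        {
            "unigene": [r.unigene_id for r in results],
            f"y_{s1}": [r.y[0] for r in results],
            f"y_{s2}": [r.y[1] for r in results],
            "logFC": [r.logfc for r in results],
            "pvalue": [r.pvalue for r in results],
            "padj_BH": [r.padj for r in results],
            "significant": [r.significant for r in results],
        }
    )
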