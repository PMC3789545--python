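"""Likelihood-ratio tests on fitted transcript sets.

Two tests share one recipe — refit the abundances under a restriction and
compare negative log-likelihoods:

* *transcript confidence*: how much worse does the model explain the data
  when transcript t's abundance is forced to zero in every sample?  The
  statistic 2*[NLL(W | W_t = 0) - NLL(W)] is referred to a chi-square with
  df = R (one freed abundance per sample; configurable).
* *differential expression*: for two samples, compare free per-sample
  abundances against abundances tied across the samples; df = number of
  tested transcripts.

Regularizers are zeroed for both tests (pure quantification), fits use the
convex proxy loss, and the reported NLLs are the exact (non-proxy) NB
likelihoods evaluated at the proxy-optimal abundances, so test calibration
does not inherit proxy fitting error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .graph import ObservationSet
from .loss import LossModel
from .solver import AbundanceMatrix, Quantifier, TranscriptSet


def transcript_confidence(
    transcript_set: TranscriptSet,
    observations: ObservationSet,
    loss_model: LossModel,
    w_intron: float = 1.0,
    df: int = None,
) -> pd.DataFrame:
    """Per-transcript likelihood-ratio confidence report.

    Returns a DataFrame with one row per transcript: the statistic
    (twice the NLL increase when the transcript is removed), degrees of
    freedom, p-value, and the model NLL with and without the transcript.
    An empty transcript set yields an empty report.
    """
    k = transcript_set.k
    n_samples = observations.n_samples
    df = n_samples if df is None else df
    columns = ["transcript", "statistic", "df", "p_value", "nll_full", "nll_restricted"]
    if k == 0:
        return pd.DataFrame(columns=columns)

    quantifier = Quantifier(observations, loss_model, w_intron)
    abund_full, _ = quantifier.fit(transcript_set)
    nll_full = quantifier.exact_nll(transcript_set, abund_full)

    rows = []
    for t in range(k):
        keep = [i for i in range(k) if i != t]
        restricted = TranscriptSet(
            U=transcript_set.U[keep],
            provenance=[transcript_set.provenance[i] for i in keep],
            edge_usage=transcript_set.edge_usage[keep],
        )
        abund_restr, _ = quantifier.fit(restricted)
        nll_restr = quantifier.exact_nll(restricted, abund_restr)
        stat = max(0.0, 2.0 * (nll_restr - nll_full))
        rows.append(
            {
                "transcript": t,
                "statistic": stat,
                "df": df,
                "p_value": float(chi2.sf(stat, df)),
                "nll_full": nll_full,
                "nll_restricted": nll_restr,
            }
        )
    return pd.DataFrame(rows, columns=columns)


def diff_expression_test(
    transcript_set: TranscriptSet,
    observations: ObservationSet,
    loss_model: LossModel,
    subset=None,
    w_intron: float = 1.0,
):
    """Two-sample test for differential transcript expression.

    Compares the free model (independent abundances per sample) against
    the null that ties abundances across the two samples — for all
    transcripts, or only those in ``subset`` (the rest stay free under the
    null).  Returns ``(statistic, df, p_value)``; df equals the number of
    tested transcripts.
    """
    if observations.n_samples != 2:
        raise ValueError(
            "differential expression test requires exactly two samples "
            "(use ObservationSet.subset_samples to select them)"
        )
    k = transcript_set.k
    tested = sorted(subset) if subset is not None else list(range(k))
    if not tested:
        raise ValueError("no transcripts selected for testing")

    quantifier = Quantifier(observations, loss_model, w_intron)
    abund_free, _ = quantifier.fit(transcript_set)
    nll_free = quantifier.exact_nll(transcript_set, abund_free)
    abund_tied = _fit_partially_tied(quantifier, transcript_set, tested)
    nll_tied = quantifier.exact_nll(transcript_set, abund_tied)

    stat = max(0.0, 2.0 * (nll_tied - nll_free))
    df = len(tested)
    return stat, df, float(chi2.sf(stat, df))


def _fit_partially_tied(quantifier: Quantifier, transcript_set: TranscriptSet, tied_rows):
    """Proxy-loss fit with the ``tied_rows`` abundances shared across both
    samples and the remaining rows free per sample."""
    k = transcript_set.k
    tied_rows = list(tied_rows)
    free_rows = [i for i in range(k) if i not in tied_rows]
    u_mat = transcript_set.U.astype(float)
    edge_use = transcript_set.edge_usage.astype(float)
    n_tied, n_free = len(tied_rows), len(free_rows)

    def unpack(x):
        w_mat = np.zeros((k, 2))
        w_mat[tied_rows, 0] = x[:n_tied]
        w_mat[tied_rows, 1] = x[:n_tied]
        w_mat[free_rows, 0] = x[n_tied : n_tied + n_free]
        w_mat[free_rows, 1] = x[n_tied + n_free :]
        return w_mat

    def fun(x):
        w_mat = unpack(x)
        total = 0.0
        grad = np.zeros_like(x)
        for r in (0, 1):
            loss, g = quantifier._sample_loss_grad(r, u_mat, edge_use, w_mat[:, r])
            total += loss
            grad[:n_tied] += g[tied_rows]
            if r == 0:
                grad[n_tied : n_tied + n_free] += g[free_rows]
            else:
                grad[n_tied + n_free :] += g[free_rows]
        return total, grad

    x0 = np.full(n_tied + 2 * n_free, 0.1)
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, quantifier.w_max)] * len(x0),
    )
    return AbundanceMatrix(W=unpack(np.maximum(res.x, 0.0)), c=quantifier.c)
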