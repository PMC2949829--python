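"""From-scratch gene set enrichment analysis with gene-set permutation.

Genes are ranked by signal-to-noise between two phenotype classes; a gene
set's enrichment score (ES) is the signed extremum of the weighted
hit-or-miss running sum down the ranked list. The null distribution is built
by scoring random gene sets of the same size (gene-set permutation — the
only calibrated choice at three animals per group), from which the nominal
p, the normalized ES and an FDR q per set are derived. A set is called
significant when p < 0.05 and FDR q < 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diffexpr import GeneSet
from .errors import DesignError, EvaluationError
from .preprocess import ExpressionMatrix

log = logging.getLogger(__name__)

P_MAX_DEFAULT = 0.05
FDR_MAX_DEFAULT = 0.25

#: Class standard deviations are floored at this fraction of |class mean|
#: (and at the fraction itself when the mean is zero).
SN_SD_FLOOR_FRACTION = 0.2


@dataclass
class RankedList:
    """Genes sorted by descending signal-to-noise score.

    Ties are broken by gene id (ascending), so the order — and therefore the
    ES — is deterministic.
    """

    genes: np.ndarray
    scores: np.ndarray
    class_a: tuple[str, ...]
    class_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("ranked list has duplicate gene ids")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    """Enrichment outcome for one (gene set, evaluation context) pair."""

    set_name: str
    context: tuple[str, str]
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    n_genes_matched: int
    significant: bool
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Probe -> gene collapse
# ---------------------------------------------------------------------------

def collapse_probes(matrix: ExpressionMatrix, how: str = "max_mean") -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene.

    ``max_mean`` (default) keeps the probe with the highest mean value;
    ``mean``/``median`` aggregate across a gene's probes. Rows are returned
    sorted by gene id. A gene-level matrix passes through unchanged.
    """
    if matrix.gene_map is None:
        return matrix
    vals = matrix.values.copy()
    genes = matrix.gene_map.reindex(vals.index)
    if how == "max_mean":
        mean = vals.mean(axis=1, skipna=True)
        order = pd.DataFrame({"gene": genes, "mean": mean})
        # stable sort keeps first probe on exact mean ties
        best = (order.sort_values(["gene", "mean"],
                                  ascending=[True, False], kind="mergesort")
                .groupby("gene", sort=True).head(1))
        out = vals.loc[best.index]
        out.index = pd.Index(best["gene"].to_numpy(), name="gene_id")
    elif how in ("mean", "median"):
        grouped = vals.groupby(genes.to_numpy(), sort=True)
        out = grouped.mean() if how == "mean" else grouped.median()
        out.index.name = "gene_id"
    else:
        raise ValueError(f"unknown collapse method {how!r}")
    from dataclasses import replace
    return replace(matrix, values=out, gene_map=None)


# ---------------------------------------------------------------------------
# Signal-to-noise ranking
# ---------------------------------------------------------------------------

def signal_to_noise_rank(
    matrix: ExpressionMatrix,
    class_a: Sequence[str],
    class_b: Sequence[str],
    collapse: str = "max_mean",
) -> RankedList:
    """Rank genes by (mu_A - mu_B) / (sd_A + sd_B), descending.

    Each class standard deviation is floored at 0.2*|class mean| (at 0.2 when
    the mean is zero). Rows with fewer than 2 usable samples in a class are
    dropped with a log message.
    """
    if len(class_a) < 2 or len(class_b) < 2:
        raise DesignError("signal-to-noise needs >=2 samples per class")
    gm = collapse_probes(matrix, how=collapse)
    a = gm.values[list(class_a)].to_numpy(dtype=float)
    b = gm.values[list(class_b)].to_numpy(dtype=float)
    na = (~np.isnan(a)).sum(axis=1)
    nb = (~np.isnan(b)).sum(axis=1)
    usable = (na >= 2) & (nb >= 2)
    if (~usable).any():
        log.info("signal-to-noise: dropped %d genes with <2 usable samples",
                 int((~usable).sum()))
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        sa = np.nanstd(a, axis=1, ddof=1)
        sb = np.nanstd(b, axis=1, ddof=1)
    sa = np.maximum(sa, _sd_floor(ma))
    sb = np.maximum(sb, _sd_floor(mb))
    score = (ma - mb) / (sa + sb)

    genes = np.asarray(gm.values.index, dtype=object)[usable]
    score = score[usable]
    order = np.lexsort((genes, -score))
    return RankedList(genes=genes[order], scores=score[order],
                      class_a=tuple(class_a), class_b=tuple(class_b))


def _sd_floor(mean: np.ndarray) -> np.ndarray:
    floor = SN_SD_FLOOR_FRACTION * np.abs(mean)
    return np.where(mean == 0, SN_SD_FLOOR_FRACTION, floor)


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

@dataclass
class EsProfile:
    es: float
    running_sum: np.ndarray
    hit_positions: np.ndarray  # 0-based indices into the ranked list


#: |max deviation| == |min deviation| ties are resolved to the positive side;
#: the comparison uses this slack so float accumulation order cannot flip it.
ES_TIE_TOLERANCE = 1e-9


def _pick_extremum(max_dev: float, min_dev: float) -> float:
    """ES = the deviation of larger magnitude; positive wins ties.

    Clipped to [-1, 1]: float accumulation can overshoot by ~1 ulp.
    """
    es = max_dev if max_dev + min_dev >= -ES_TIE_TOLERANCE else min_dev
    return min(1.0, max(-1.0, es))


def _es_from_hits(abs_scores_w: np.ndarray, hits: np.ndarray, n: int) -> float:
    """ES from sorted 0-based hit positions, without materializing the sum.

    ``abs_scores_w`` holds |score|^weight for the whole ranked list. The
    running-sum extrema can only occur immediately after a hit (maximum
    candidates) or immediately before a hit / at the very end (minimum
    candidates), which keeps this O(k) per evaluation.
    """
    k = len(hits)
    if k == 0 or k >= n:
        raise EvaluationError("hit count must be in [1, n_genes)")
    w = abs_scores_w[hits]
    nr = float(w.sum())
    miss = 1.0 / (n - k)
    inc = w / nr if nr > 0 else np.zeros(k)
    cw = np.cumsum(inc)
    # misses accumulated up to and including position hits[i] (exclusive of
    # the i+1 hits seen so far): hits[i] - i
    misses_before = (hits - np.arange(k)) * miss
    top = cw - misses_before
    bot = top - inc
    end = (cw[-1] if nr > 0 else 0.0) - (n - k) * miss
    max_dev = float(top.max())
    min_dev = float(min(bot.min(), end))
    return _pick_extremum(max_dev, min_dev)


def enrichment_score(
    ranked: RankedList,
    gene_set: GeneSet | Iterable[str],
    weight: float = 1.0,
) -> EsProfile:
    """Weighted running-sum enrichment score of one gene set.

    Hits add |score|^weight / N_R (N_R = sum over hits), misses subtract
    1/(N - N_H); the ES is the running sum's signed maximum deviation from
    zero, always in [-1, 1].
    """
    members = set(gene_set.members if isinstance(gene_set, GeneSet)
                  else gene_set)
    hit_mask = np.isin(ranked.genes, list(members))
    n = len(ranked)
    k = int(hit_mask.sum())
    name = gene_set.name if isinstance(gene_set, GeneSet) else "<set>"
    if k == 0:
        raise EvaluationError(f"gene set {name!r}: no member in ranked list")
    if k == n:
        raise EvaluationError(f"gene set {name!r} covers the entire list")

    absw = np.abs(ranked.scores) ** weight
    nr = float(absw[hit_mask].sum())
    steps = np.where(hit_mask,
                     absw / nr if nr > 0 else 0.0,
                     -1.0 / (n - k))
    running = np.cumsum(steps)
    es = _pick_extremum(float(running.max()), float(running.min()))
    return EsProfile(es=es, running_sum=running,
                     hit_positions=np.flatnonzero(hit_mask))


# ---------------------------------------------------------------------------
# Gene-set permutation null, nominal p, NES and FDR
# ---------------------------------------------------------------------------

def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    weight: float = 1.0,
) -> np.ndarray:
    """ES sample of ``n_perm`` random same-size gene sets.

    Sets are drawn uniformly without replacement from the ranked universe
    with a seeded generator, so the sample is reproducible.
    """
    n = len(ranked)
    if not 0 < set_size < n:
        raise DesignError(
            f"set_size must be in (0, {n}); got {set_size}")
    if n_perm < 1:
        raise DesignError("n_perm must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    absw = np.abs(ranked.scores) ** weight
    out = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7 // n)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        idx.sort(axis=1)
        for r in range(m):
            out[done + r] = _es_from_hits(absw, idx[r], n)
        done += m
    return out


def nominal_p(es: float, null: np.ndarray) -> float:
    """Same-sign tail probability of the observed ES in the permutation null.

    For ES >= 0, p = #{pi : ES_pi >= ES} / #{pi : ES_pi >= 0} (mirrored for
    negative ES); 0.0 is reported when no permuted score reaches the
    observed. With no same-sign permuted score at all, p falls back to
    1/(n_perm + 1) with a warning.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise DesignError("empty permutation sample")
    if es >= 0:
        side = null[null >= 0]
        extreme = int((side >= es).sum())
    else:
        side = null[null < 0]
        extreme = int((side <= es).sum())
    if side.size == 0:
        log.warning("no same-sign permuted scores; p set to 1/(n_perm+1)")
        return 1.0 / (null.size + 1)
    return extreme / side.size


def _normalize(es: float, null: np.ndarray) -> tuple[float, np.ndarray]:
    """NES of the observed ES plus the normalized null sample.

    Each score is divided by the mean magnitude of the same-sign permuted
    scores. Returns (nan, normalized null) when the observed side of the
    null is degenerate.
    """
    pos = null[null >= 0]
    neg = null[null < 0]
    mpos = float(pos.mean()) if pos.size else 0.0
    mneg = float(np.abs(neg).mean()) if neg.size else 0.0
    parts = []
    if pos.size and mpos > 0:
        parts.append(pos / mpos)
    if neg.size and mneg > 0:
        parts.append(neg / mneg)
    null_nes = np.concatenate(parts) if parts else np.empty(0)
    if es >= 0:
        nes = es / mpos if mpos > 0 else float("nan")
    else:
        nes = es / mneg if mneg > 0 else float("nan")
    return nes, null_nes


def nes_and_fdr(
    entries: Sequence[tuple[str, tuple[str, str], float, np.ndarray, float, int]],
    p_max: float = P_MAX_DEFAULT,
    fdr_max: float = FDR_MAX_DEFAULT,
) -> list[GseaResult]:
    """Normalize a batch of results and attach FDR q values.

    Each entry is (set name, context, ES, null ES sample, nominal p,
    n matched). NES = ES / mean(|same-sign permuted ES|). The q value is the
    ratio of the same-sign tail fraction of the pooled permuted NES to the
    same-sign tail fraction of the observed NES, capped at 1 and made
    monotone in |NES| within each sign. A set whose null side is degenerate
    gets NaN NES/q and is flagged, never significant.
    """
    if not entries:
        raise DesignError("nes_and_fdr needs at least one entry")
    nes_obs: list[float] = []
    null_nes_all: list[np.ndarray] = []
    for _, _, es, null, _, _ in entries:
        nes, null_nes = _normalize(es, np.asarray(null, dtype=float))
        nes_obs.append(nes)
        null_nes_all.append(null_nes)
    pooled = (np.concatenate(null_nes_all) if null_nes_all
              else np.empty(0))
    obs = np.array(nes_obs, dtype=float)
    valid = np.isfinite(obs)

    q_raw = np.full(len(obs), np.nan)
    n_pool_pos = int((pooled >= 0).sum())
    n_pool_neg = int((pooled < 0).sum())
    n_obs_pos = int((obs[valid] >= 0).sum())
    n_obs_neg = int((obs[valid] < 0).sum())
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            frac_null = ((pooled >= nes).sum() / n_pool_pos
                         if n_pool_pos else 1.0)
            frac_obs = (obs[valid] >= nes).sum() / n_obs_pos
        else:
            frac_null = ((pooled <= nes).sum() / n_pool_neg
                         if n_pool_neg else 1.0)
            frac_obs = (obs[valid] <= nes).sum() / n_obs_neg
        q_raw[i] = min(1.0, frac_null / frac_obs)

    # monotone in extremity: a more extreme NES never gets a larger q
    # (running minimum over less extreme sets, as in step-up FDR)
    q = q_raw.copy()
    for sign in (1, -1):
        idx = [i for i in range(len(obs))
               if np.isfinite(obs[i]) and (obs[i] >= 0) == (sign == 1)]
        idx.sort(key=lambda i: abs(obs[i]))  # least extreme first
        running = np.inf
        for i in idx:
            running = min(running, q_raw[i])
            q[i] = running

    results = []
    for i, (name, context, es, null, p, n_matched) in enumerate(entries):
        degenerate = not np.isfinite(obs[i])
        if degenerate:
            log.warning("set %r: degenerate permutation null, NES undefined",
                        name)
        significant = (not degenerate) and p < p_max and q[i] < fdr_max
        results.append(GseaResult(
            set_name=name,
            context=context,
            es=float(es),
            nes=float(obs[i]),
            p_nominal=float(p),
            fdr_q=float(q[i]) if not degenerate else float("nan"),
            n_genes_matched=int(n_matched),
            significant=bool(significant),
            degenerate=degenerate,
        ))
    return results


# ---------------------------------------------------------------------------
# One-call evaluation of a batch of sets in one context
# ---------------------------------------------------------------------------

def run_gsea(
    matrix: ExpressionMatrix,
    class_a: Sequence[str],
    class_b: Sequence[str],
    gene_sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    collapse: str = "max_mean",
    context: tuple[str, str] | None = None,
    p_max: float = P_MAX_DEFAULT,
    fdr_max: float = FDR_MAX_DEFAULT,
) -> list[GseaResult]:
    """Rank once, score every set, and compute p/NES/FDR jointly.

    Permutation nulls are cached per matched-set size, so same-size sets
    share one null sample within a call.
    """
    if not gene_sets:
        raise DesignError("run_gsea needs at least one gene set")
    ranked = signal_to_noise_rank(matrix, class_a, class_b, collapse=collapse)
    ctx = context or (",".join(class_a), ",".join(class_b))
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    entries = []
    for gs in gene_sets:
        profile = enrichment_score(ranked, gs, weight=weight)
        size = len(profile.hit_positions)
        if size not in null_cache:
            null_cache[size] = permutation_null(
                ranked, size, n_perm=n_perm, seed=rng, weight=weight)
        null = null_cache[size]
        p = nominal_p(profile.es, null)
        entries.append((gs.name, ctx, profile.es, null, p, size))
    return nes_and_fdr(entries, p_max=p_max, fdr_max=fdr_max)
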