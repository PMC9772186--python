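"""Host population structure: genotype curation, admixture, lineages, FST, PCA.

Works on diploid genotypes of either marker system used for *Porites* cf.
*lobata* — multiallelic microsatellites (fragment sizes with peak heights,
possibly replicated runs) and biallelic SNPs from a VCF.  The pipeline is:

1. resolve multi-allele microsatellite cells to two alleles (three-rule
   curation), 2. drop high-missingness loci (>40%) then under-genotyped
   samples (<10 of the remaining loci), 3. estimate individual ancestry
   proportions Q under a K-population admixture model by maximum likelihood
   (EM with restarts), 4. assign each colony to its majority lineage
   (>50% ancestry) or "admixed", 5. quantify divergence with multi-locus
   Nei's FST (1 - sum Hs / sum Ht) with a locus bootstrap, and 6. summarize
   structure with a genotype PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "AncestryMatrix",
    "FstMatrix",
    "FilterReport",
    "PcaResult",
    "curate_microsatellites",
    "filter_loci_samples",
    "estimate_admixture",
    "admixture_k_scan",
    "assign_lineage",
    "match_labels",
    "concordance",
    "nei_fst",
    "genotype_pca",
]

MISSING = -1
ADMIXED = "admixed"


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x loci diploid genotype calls.

    ``calls`` is an ``(n, L, 2)`` integer array of allele indices into the
    per-locus allele universe ``alleles`` (labels: REF/ALT strings for SNPs,
    fragment sizes in bp for microsatellites); ``-1`` in both slots marks a
    missing cell.  Cells are unordered pairs; homozygotes carry a doubled
    allele.  ``metadata`` (optional) is indexed by sample id and typically
    carries site and habitat.
    """

    samples: list[str]
    loci: list[str]
    alleles: list[list]
    calls: np.ndarray = field(repr=False)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int32)
        object.__setattr__(self, "calls", calls)
        n, L = len(self.samples), len(self.loci)
        if calls.shape != (n, L, 2):
            raise ValueError(f"calls must have shape ({n}, {L}, 2)")
        if len(self.alleles) != L:
            raise ValueError("one allele universe required per locus")
        for l in range(L):
            m = len(self.alleles[l])
            col = calls[:, l, :]
            if col.max(initial=-1) >= m:
                raise ValueError(f"locus {self.loci[l]}: allele index outside universe")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the cell is missing."""
        return self.calls[:, :, 0] == MISSING

    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        meta = None
        if self.metadata is not None:
            keep = [self.samples[i] for i in si]
            meta = self.metadata.loc[[s for s in keep if s in self.metadata.index]]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            loci=[self.loci[i] for i in li],
            alleles=[self.alleles[i] for i in li],
            calls=self.calls[np.ix_(si, li)],
            metadata=meta,
        )

    def allele_dosage(self) -> tuple[np.ndarray, np.ndarray]:
        """One-hot allele-count encoding.

        Returns ``(X, locus_of_col)`` where ``X`` is ``(n, J)`` with
        ``J = sum of per-locus allele counts``; ``X[i, j]`` is the number of
        copies (0/1/2) of allele ``j`` carried by individual ``i``, all zeros
        across a locus's columns when the cell is missing.
        """
        sizes = np.array([len(a) for a in self.alleles])
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        J = int(offsets[-1])
        X = np.zeros((self.n_samples, J), dtype=np.float64)
        locus_of_col = np.repeat(np.arange(self.n_loci), sizes)
        for l in range(self.n_loci):
            cell = self.calls[:, l, :]
            ok = cell[:, 0] != MISSING
            for c in range(2):
                idx = np.flatnonzero(ok)
                np.add.at(X, (idx, offsets[l] + cell[idx, c]), 1.0)
        return X, locus_of_col


@dataclass(frozen=True)
class FilterReport:
    """Record of loci and samples removed by missingness filtering."""

    removed_loci: list[tuple[str, float]]
    removed_samples: list[tuple[str, int]]
    n_loci_in: int
    n_samples_in: int

    @property
    def n_loci_out(self) -> int:
        return self.n_loci_in - len(self.removed_loci)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - len(self.removed_samples)

    def __str__(self) -> str:
        lines = [
            f"loci: {self.n_loci_in} in, {len(self.removed_loci)} removed, {self.n_loci_out} retained",
            f"samples: {self.n_samples_in} in, {len(self.removed_samples)} removed, {self.n_samples_out} retained",
        ]
        for name, rate in self.removed_loci:
            lines.append(f"  locus {name} removed: missingness {rate:.1%}")
        for name, k in self.removed_samples:
            lines.append(f"  sample {name} removed: genotyped at only {k} loci")
        return "\n".join(lines)


@dataclass(frozen=True)
class AncestryMatrix:
    """Admixture fit: ancestry proportions Q and allele frequencies P.

    ``Q`` is ``(n, K)`` (rows on the simplex); ``P`` is ``(K, J)`` over the
    flattened per-locus allele columns of :meth:`GenotypeMatrix.allele_dosage`
    (each locus block sums to 1 per population).  ``loglik_trace`` is the
    non-decreasing log-likelihood of the best restart.
    """

    samples: list[str]
    Q: np.ndarray = field(repr=False)
    P: np.ndarray = field(repr=False)
    K: int
    locus_of_col: np.ndarray = field(repr=False)
    loglik: float
    loglik_trace: np.ndarray = field(repr=False)
    converged: bool
    n_restarts: int
    seed: int | None

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")


@dataclass(frozen=True)
class FstMatrix:
    """Pairwise multi-locus Nei's FST between groups, with bootstrap CIs."""

    labels: list[str]
    fst: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_loci: np.ndarray
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fst, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class PcaResult:
    """Genotype PCA coordinates and explained-variance fractions."""

    samples: list[str]
    coords: np.ndarray = field(repr=False)
    explained_variance_ratio: np.ndarray = field(repr=False)
    excluded: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Microsatellite curation
# ---------------------------------------------------------------------------

def _provisional_frequencies(raw: pd.DataFrame) -> dict[str, dict]:
    """Per-locus allele frequencies from unambiguous cells (<= 2 distinct
    alleles across all runs); first pass of the two-pass curation."""
    freqs: dict[str, dict] = {}
    for locus, by_locus in raw.groupby("locus", sort=False):
        counts: dict = {}
        for _, cell in by_locus.groupby("sample", sort=False):
            distinct = sorted(cell["allele_size"].unique())
            if 0 < len(distinct) <= 2:
                if len(distinct) == 1:
                    distinct = distinct * 2
                for a in distinct:
                    counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        freqs[locus] = {a: c / total for a, c in counts.items()} if total else {}
    return freqs


def _resolve_cell(cell: pd.DataFrame, freqs: dict) -> list:
    """Apply the three-rule multi-allele curation to one sample x locus cell.

    Rule 1: with replicate runs, an allele seen in only one run is dropped.
    Rule 2: in single-run cells, a third allele whose peak height is less
    than half the second-highest peak is dropped.
    Rule 3: any remaining cell with more than two alleles keeps the two
    alleles most frequent in the whole dataset (rarest dropped).
    """
    runs = list(cell.groupby("run", sort=False))
    alleles = sorted(cell["allele_size"].unique())
    if len(alleles) <= 2:
        return alleles

    if len(runs) > 1:
        seen_in = {
            a: sum(1 for _, r in runs if a in set(r["allele_size"])) for a in alleles
        }
        replicated = [a for a in alleles if seen_in[a] >= 2]
        if replicated:
            alleles = replicated
        if len(alleles) <= 2:
            return alleles
    else:
        heights = cell.groupby("allele_size")["peak_height"].max()
        ranked = heights.sort_values(ascending=False)
        if len(ranked) >= 3:
            second = float(ranked.iloc[1])
            kept = [a for a, h in ranked.items() if h >= 0.5 * second]
            # the two tallest peaks always survive the half-height rule
            alleles = sorted(set(kept) | set(ranked.index[:2]))
        if len(alleles) <= 2:
            return sorted(alleles)

    # Rule 3: keep the two alleles with highest dataset-wide frequency.
    heights = cell.groupby("allele_size")["peak_height"].max()
    ranked = sorted(
        alleles,
        key=lambda a: (-freqs.get(a, 0.0), -float(heights.get(a, 0.0)), a),
    )
    return sorted(ranked[:2])


def curate_microsatellites(
    raw: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Resolve raw fragment-analysis calls to <= 2 alleles per cell.

    ``raw`` needs columns ``sample, locus, run, allele_size, peak_height``
    (one row per called peak).  Dataset-wide allele frequencies used by rule 3
    are computed in a first pass over unambiguous cells only.  Cells with a
    single surviving allele become homozygotes; cells with none become
    missing (logged).
    """
    req = {"sample", "locus", "run", "allele_size", "peak_height"}
    if not req <= set(raw.columns):
        raise ValueError(f"raw calls need columns {sorted(req)}")
    if (raw["peak_height"] <= 0).any():
        raise ValueError("peak heights must be positive")

    freqs = _provisional_frequencies(raw)
    samples = list(pd.unique(raw["sample"]))
    loci = list(pd.unique(raw["locus"]))
    genotypes: dict[tuple[str, str], list] = {}
    universes: dict[str, set] = {l: set() for l in loci}

    for (sample, locus), cell in raw.groupby(["sample", "locus"], sort=False):
        kept = _resolve_cell(cell, freqs[locus])
        if not kept:
            logger.warning("cell %s x %s: no surviving alleles, set missing", sample, locus)
            continue
        if len(kept) == 1:
            kept = kept * 2
        genotypes[(sample, locus)] = kept
        universes[locus].update(kept)

    allele_lists = [sorted(universes[l]) for l in loci]
    index = [{a: i for i, a in enumerate(al)} for al in allele_lists]
    calls = np.full((len(samples), len(loci), 2), MISSING, dtype=np.int32)
    for (sample, locus), pair in genotypes.items():
        i, l = samples.index(sample), loci.index(locus)
        calls[i, l] = [index[l][pair[0]], index[l][pair[1]]]
    return GenotypeMatrix(
        samples=samples, loci=loci, alleles=allele_lists, calls=calls, metadata=metadata
    )


def filter_loci_samples(
    g: GenotypeMatrix,
    max_locus_missing: float = 0.40,
    min_loci_per_sample: int = 10,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Missingness filtering: loci first, then samples.

    Loci with missingness strictly above ``max_locus_missing`` are removed;
    samples genotyped at fewer than ``min_loci_per_sample`` of the *remaining*
    loci are then removed (this order follows standard marker curation:
    unreliable loci should not count against samples).
    """
    miss = g.missing_mask()
    locus_rate = miss.mean(axis=0)
    keep_loci = np.flatnonzero(locus_rate <= max_locus_missing)
    removed_loci = [
        (g.loci[l], float(locus_rate[l]))
        for l in range(g.n_loci)
        if locus_rate[l] > max_locus_missing
    ]
    if keep_loci.size == 0:
        raise ValueError("all loci removed by missingness filter")

    genotyped = (~miss[:, keep_loci]).sum(axis=1)
    keep_samples = np.flatnonzero(genotyped >= min_loci_per_sample)
    removed_samples = [
        (g.samples[i], int(genotyped[i]))
        for i in range(g.n_samples)
        if genotyped[i] < min_loci_per_sample
    ]
    out = g.subset(keep_samples, keep_loci)
    report = FilterReport(
        removed_loci=removed_loci,
        removed_samples=removed_samples,
        n_loci_in=g.n_loci,
        n_samples_in=g.n_samples,
    )
    return out, report


# ---------------------------------------------------------------------------
# Admixture model (maximum likelihood, EM)
# ---------------------------------------------------------------------------

_P_FLOOR = 1e-9


def _locus_normalize(M: np.ndarray, locus_of_col: np.ndarray) -> np.ndarray:
    """Normalize each locus block of (K, J) rows to sum to 1, with a floor."""
    n_loci = int(locus_of_col.max()) + 1
    starts = np.searchsorted(locus_of_col, np.arange(n_loci))
    sums = np.add.reduceat(M, starts, axis=1)
    M = M / sums[:, locus_of_col]
    M = np.clip(M, _P_FLOOR, None)
    sums = np.add.reduceat(M, starts, axis=1)
    return M / sums[:, locus_of_col]


def _em_fit(X, locus_of_col, copies, K, Q0, P0, max_iter, tol):
    Q, P = Q0, P0
    trace = []
    prev = -np.inf
    converged = False
    nz = X > 0
    for _ in range(max_iter):
        F = Q @ P  # (n, J) expected allele frequency per individual
        F = np.maximum(F, 1e-300)
        ll = float(np.sum(X[nz] * np.log(F[nz])))
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        R = np.where(nz, X / F, 0.0)  # (n, J)
        Q = Q * (R @ P.T)
        Q /= np.maximum(copies[:, None], 1.0)
        Q = np.clip(Q, 1e-12, None)
        Q /= Q.sum(axis=1, keepdims=True)
        P = _locus_normalize(P * (Q.T @ R), locus_of_col)
    return Q, P, np.asarray(trace), converged


def estimate_admixture(
    g: GenotypeMatrix,
    K: int,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-3,
    seed: int | None = None,
) -> AncestryMatrix:
    """Maximum-likelihood admixture fit for K source populations.

    Maximizes the admixture log-likelihood
    ``sum over gene copies of log sum_k q_ik p_k,locus,allele`` by EM
    (block-relaxation updates of Q and P), taking the best of ``n_restarts``
    random restarts by final log-likelihood.  Missing cells contribute
    nothing.  Convergence: log-likelihood gain below ``tol``; if not reached
    within ``max_iter``, the fit is returned with ``converged=False`` and a
    logged warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if g.n_samples < K:
        raise ValueError(f"need at least K={K} individuals")
    X, locus_of_col = g.allele_dosage()
    copies = X.sum(axis=1)  # 2 * number of genotyped loci per individual
    n, J = X.shape

    # Observed pooled frequencies, the anchor for P initialization.
    pooled = X.sum(axis=0)
    pooled = _locus_normalize(pooled[None, :].repeat(K, axis=0), locus_of_col)

    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(child)
        Q0 = rng.dirichlet(np.ones(K), size=n)
        P0 = _locus_normalize(
            pooled * rng.uniform(0.2, 1.8, size=pooled.shape), locus_of_col
        )
        fit = _em_fit(X, locus_of_col, copies, K, Q0, P0, max_iter, tol)
        if best is None or fit[2][-1] > best[2][-1]:
            best = fit
    Q, P, trace, converged = best
    if not converged:
        logger.warning("admixture EM did not converge in %d iterations", max_iter)
    return AncestryMatrix(
        samples=list(g.samples),
        Q=Q,
        P=P,
        K=K,
        locus_of_col=locus_of_col,
        loglik=float(trace[-1]),
        loglik_trace=trace,
        converged=converged,
        n_restarts=n_restarts,
        seed=seed,
    )


def admixture_k_scan(
    g: GenotypeMatrix,
    ks: list[int],
    **kwargs,
) -> pd.DataFrame:
    """Fit the admixture model for several K and report a BIC curve.

    A lightweight aid for choosing K: BIC = -2 loglik + params * log(gene
    copies), params = n(K-1) + K * sum_l (m_l - 1).  Lower is better.
    """
    rows = []
    n_copies = float((~g.missing_mask()).sum()) * 2
    m = np.array([len(a) for a in g.alleles])
    for K in ks:
        fit = estimate_admixture(g, K, **kwargs)
        params = g.n_samples * (K - 1) + K * int((m - 1).sum())
        rows.append(
            {"K": K, "loglik": fit.loglik, "n_params": params,
             "bic": -2 * fit.loglik + params * np.log(n_copies)}
        )
    return pd.DataFrame(rows)


def assign_lineage(
    a: AncestryMatrix,
    threshold: float = 0.5,
    names: list[str] | None = None,
) -> pd.Series:
    """Majority-rule lineage assignment.

    Each individual gets the lineage with its largest ancestry proportion if
    that proportion strictly exceeds ``threshold`` (default 0.5, the >50%
    majority rule), else the label ``"admixed"``.
    """
    if names is None:
        names = [f"L{k + 1}" for k in range(a.K)]
    if len(names) != a.K:
        raise ValueError("need one name per cluster")
    top = a.Q.argmax(axis=1)
    labels = [
        names[k] if a.Q[i, k] > threshold else ADMIXED for i, k in enumerate(top)
    ]
    return pd.Series(labels, index=a.samples, name="lineage")


def match_labels(Q_est: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Permutation of the columns of ``Q_est`` best matching ``Q_ref``.

    Resolves admixture label switching by maximum-agreement bipartite
    assignment on the overlap matrix ``Q_est.T @ Q_ref``.  Returns ``perm``
    such that ``Q_est[:, perm]`` aligns with ``Q_ref``.
    """
    overlap = Q_est.T @ Q_ref
    rows, cols = linear_sum_assignment(-overlap)
    perm = np.empty(Q_est.shape[1], dtype=int)
    perm[cols] = rows
    return perm


def concordance(
    labels_a: pd.Series,
    labels_b: pd.Series,
) -> tuple[float, dict, int]:
    """Agreement between two cluster labelings of overlapping individuals.

    Label names are matched by maximum-agreement bipartite assignment, so a
    pure renaming of clusters scores 100%.  Individuals labeled "admixed" in
    either set are excluded from the agreement fraction and counted
    separately.  Returns ``(agreement, label_map b->a, n_admixed_excluded)``.
    """
    shared = labels_a.index.intersection(labels_b.index)
    if len(shared) == 0:
        raise ValueError("no overlapping individuals between labelings")
    la, lb = labels_a.loc[shared], labels_b.loc[shared]
    admixed = (la == ADMIXED) | (lb == ADMIXED)
    la, lb = la[~admixed], lb[~admixed]
    if len(la) == 0:
        return float("nan"), {}, int(admixed.sum())
    table = pd.crosstab(lb, la)
    rows, cols = linear_sum_assignment(-table.to_numpy())
    mapping = {table.index[r]: table.columns[c] for r, c in zip(rows, cols)}
    agree = sum(mapping.get(b) == a for a, b in zip(la, lb))
    return agree / len(la), mapping, int(admixed.sum())


# ---------------------------------------------------------------------------
# Nei's FST
# ---------------------------------------------------------------------------

def _group_frequencies(g: GenotypeMatrix, idx: np.ndarray):
    """Per-locus (frequency vector, genotyped count) for one group.

    Frequency entries are None when the group has no data at the locus.
    """
    freqs, counts = [], []
    for l in range(g.n_loci):
        cell = g.calls[np.asarray(idx), l, :]
        ok = cell[:, 0] != MISSING
        alleles = cell[ok].ravel()
        counts.append(int(ok.sum()))
        if alleles.size == 0:
            freqs.append(None)
            continue
        tab = np.bincount(alleles, minlength=len(g.alleles[l])).astype(float)
        freqs.append(tab / tab.sum())
    return freqs, np.asarray(counts)


def _pair_locus_h(fa, fb, na, nb):
    """Per-locus (Hs, Ht) arrays for one group pair, polymorphic loci only.

    Sample-size corrected (Nei & Chesser family): within-group gene diversity
    ``1 - sum p^2`` is scaled by ``2n / (2n - 1)`` per group, and the total
    diversity from the unweighted mean frequencies gains the term
    ``Hs / (2 * n_harmonic * 2)``, making the null expectation of FST zero
    for two samples from one population.
    """
    hs, ht = [], []
    for pa, pb, n_a, n_b in zip(fa, fb, na, nb):
        if pa is None or pb is None:
            continue
        pbar = 0.5 * (pa + pb)
        if np.max(pbar) >= 1.0 - 1e-12:  # monomorphic in the pooled pair
            continue
        h_a = (1.0 - (pa**2).sum()) * (2 * n_a) / max(2 * n_a - 1, 1)
        h_b = (1.0 - (pb**2).sum()) * (2 * n_b) / max(2 * n_b - 1, 1)
        hs_l = 0.5 * (h_a + h_b)
        n_harm = 2.0 / (1.0 / n_a + 1.0 / n_b)
        hs.append(hs_l)
        ht.append(1.0 - (pbar**2).sum() + hs_l / (4.0 * n_harm))
    return np.asarray(hs), np.asarray(ht)


def nei_fst(
    g: GenotypeMatrix,
    groups: pd.Series,
    n_boot: int = 100,
    seed: int | None = None,
    ci: float = 0.95,
) -> FstMatrix:
    """Pairwise multi-locus Nei's FST between groups with a locus bootstrap.

    For each pair of groups, per-locus within-group expected heterozygosity
    ``Hs`` (mean of the two groups) and total expected heterozygosity ``Ht``
    (from the unweighted mean allele frequencies) are accumulated over loci
    polymorphic in the pooled pair, and ``FST = 1 - sum Hs / sum Ht``, with
    the Nei & Chesser-style sample-size corrections of ``_pair_locus_h`` (so
    two samples from one population give FST centered on zero; slightly
    negative estimates are possible and left unclipped).  Percentile
    confidence intervals come from ``n_boot`` bootstrap resamples of loci.
    Pairs with no polymorphic locus get FST 0; pairs where a group has no
    data at some locus are flagged.
    """
    labels = sorted(groups.dropna().unique())
    members = {
        lab: [g.samples.index(s) for s in groups.index[groups == lab] if s in g.samples]
        for lab in labels
    }
    for lab in labels:
        if len(members[lab]) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 genotyped individuals")
    freqs = {lab: _group_frequencies(g, members[lab]) for lab in labels}  # (freqs, counts)

    k = len(labels)
    fst = np.zeros((k, k))
    lo = np.zeros((k, k))
    hi = np.zeros((k, k))
    n_used = np.zeros((k, k), dtype=int)
    flagged: list[tuple[str, str]] = []
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    for i in range(k):
        for j in range(i + 1, k):
            (fa, na), (fb, nb) = freqs[labels[i]], freqs[labels[j]]
            if any(p is None for p in fa) or any(p is None for p in fb):
                flagged.append((labels[i], labels[j]))
            hs, ht = _pair_locus_h(fa, fb, na, nb)
            n_used[i, j] = n_used[j, i] = hs.size
            if hs.size == 0:
                continue
            val = 1.0 - hs.sum() / ht.sum()
            fst[i, j] = fst[j, i] = val
            boots = np.empty(n_boot)
            for b in range(n_boot):
                pick = rng.integers(0, hs.size, size=hs.size)
                boots[b] = 1.0 - hs[pick].sum() / ht[pick].sum()
            lo[i, j] = lo[j, i] = float(np.quantile(boots, alpha))
            hi[i, j] = hi[j, i] = float(np.quantile(boots, 1.0 - alpha))
    return FstMatrix(
        labels=labels, fst=fst, ci_low=lo, ci_high=hi, n_loci=n_used,
        flagged_pairs=flagged,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def genotype_pca(g: GenotypeMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of one-hot allele counts, centered and scaled.

    Missing cells are mean-imputed per allele column; zero-variance columns
    are dropped; individuals missing at every locus are excluded with a
    warning.  Coordinates are reproducible up to sign.
    """
    if g.n_samples < 3:
        raise ValueError("PCA requires at least 3 individuals")
    X, _ = g.allele_dosage()
    miss = g.missing_mask()
    all_missing = miss.all(axis=1)
    excluded = [s for s, m in zip(g.samples, all_missing) if m]
    if excluded:
        logger.warning("PCA excludes all-missing individuals: %s", excluded)
    keep = ~all_missing
    X = X[keep]
    miss = miss[keep]
    samples = [s for s, m in zip(g.samples, all_missing) if not m]

    # NaN-out missing cells so imputation uses observed individuals only.
    sizes = np.array([len(a) for a in g.alleles])
    col_missing = np.repeat(miss, sizes, axis=1)
    X = np.where(col_missing, np.nan, X)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X) - mean
    sd = X.std(axis=0, ddof=0)
    ok = sd > 0
    X = X[:, ok] / sd[ok]

    U, S, _ = np.linalg.svd(X, full_matrices=False)
    var = S**2
    ratio = var / var.sum()
    coords = U * S
    if n_components is not None:
        coords = coords[:, :n_components]
        ratio = ratio[:n_components]
    return PcaResult(
        samples=samples,
        coords=coords,
        explained_variance_ratio=ratio,
        excluded=excluded,
    )
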