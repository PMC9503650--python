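"""Survey statistics: prevalence, morphology enrichment, co-occurrence.

All statistics operate on a list of :class:`~viranet.dataset_io.GenomeRecord`
plus a set of "positive" genome ids (those carrying at least one network
domain, or one particular family).  Prevalence is reported both as a curve
over genome-length thresholds (fraction of genomes of at least a given
length that are positive) and stratified into named size classes.  The
morphology association is a Pearson chi-square on an r x c contingency
table; pairwise family co-occurrence uses the fixed-margin hypergeometric
null with one-sided enrichment and depletion tails and Benjamini–Hochberg
correction per direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import GenomeRecord


@dataclass(frozen=True)
class SizeClassConfig:
    """Named genome-length classes, bounds in bp as half-open [lo, hi).

    The default classes deliberately leave the 25–100 kb range unclassed;
    genomes falling there are reported in an "unclassed" bucket rather than
    silently absorbed.  ``rna_rise`` and ``dna_rise`` are curve landmarks:
    the genome sizes where the prevalence of network domains rises sharply
    in RNA and DNA viruses respectively.
    """

    classes: tuple[tuple[str, float, float], ...] = (
        ("small", 0.0, 25_000.0),
        ("medium", 100_000.0, 180_000.0),
        ("jumbo", 180_000.0, math.inf),
    )
    rna_rise: float = 17_500.0
    dna_rise: float = 60_000.0

    def __post_init__(self):
        spans = sorted((lo, hi) for _, lo, hi in self.classes)
        for (lo1, hi1), (lo2, _hi2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise ValueError("size classes overlap")

    def classify(self, length: float) -> str | None:
        for name, lo, hi in self.classes:
            if lo <= length < hi:
                return name
        return None


def prevalence_curve(
    genomes: Sequence[GenomeRecord],
    positives: Iterable[str],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Fraction of genomes with length >= t that are positive, per threshold.

    Thresholds above the largest genome are omitted (empty stratum).
    Columns: threshold, n_genomes, n_positive, fraction.
    """
    pos = set(positives)
    lengths = np.array([g.genome_length for g in genomes], dtype=float)
    is_pos = np.array([g.genome_id in pos for g in genomes], dtype=bool)
    rows = []
    for t in sorted(thresholds):
        mask = lengths >= t
        n = int(mask.sum())
        if n == 0:
            continue
        npos = int(is_pos[mask].sum())
        rows.append(
            {"threshold": float(t), "n_genomes": n, "n_positive": npos, "fraction": npos / n}
        )
    return pd.DataFrame(rows, columns=["threshold", "n_genomes", "n_positive", "fraction"])


def class_prevalence(
    genomes: Sequence[GenomeRecord],
    positives: Iterable[str],
    size_classes: SizeClassConfig | None = None,
) -> pd.DataFrame:
    """Positive fraction per named size class, plus an "unclassed" bucket.

    Empty classes keep their row with n = 0 and fraction NaN (absent, not
    zero).  Columns: size_class, n_genomes, n_positive, fraction.
    """
    cfg = size_classes or SizeClassConfig()
    pos = set(positives)
    counts = {name: [0, 0] for name, _, _ in cfg.classes}
    counts["unclassed"] = [0, 0]
    for g in genomes:
        name = cfg.classify(g.genome_length) or "unclassed"
        counts[name][0] += 1
        if g.genome_id in pos:
            counts[name][1] += 1
    rows = []
    for name in [n for n, _, _ in cfg.classes] + ["unclassed"]:
        n, npos = counts[name]
        rows.append(
            {
                "size_class": name,
                "n_genomes": n,
                "n_positive": npos,
                "fraction": (npos / n) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["size_class", "n_genomes", "n_positive", "fraction"])


def per_1000(
    genomes: Sequence[GenomeRecord], positives: Iterable[str]
) -> pd.DataFrame:
    """Positives per 1000 genomes, stratified by virion morphology."""
    pos = set(positives)
    counts: dict[str, list[int]] = {}
    for g in genomes:
        counts.setdefault(g.morphology, [0, 0])
        counts[g.morphology][0] += 1
        if g.genome_id in pos:
            counts[g.morphology][1] += 1
    rows = [
        {
            "morphology": m,
            "n_genomes": n,
            "n_positive": npos,
            "per_1000": 1000.0 * npos / n,
        }
        for m, (n, npos) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["morphology", "n_genomes", "n_positive", "per_1000"])


@dataclass(frozen=True)
class EnrichmentResult:
    chi2: float
    df: int
    p_value: float
    low_expected: bool  # some expected count < 5
    fisher_p: float | None = None  # two-sided Fisher exact, 2x2 tables only


def enrichment_test(table: Sequence[Sequence[float]]) -> EnrichmentResult:
    """Pearson chi-square (no continuity correction) on an r x c table.

    Degenerate tables (a zero row or column margin) raise ValueError.  When
    any expected count falls below 5 a warning is emitted and, for 2x2
    tables, a two-sided Fisher exact p-value is reported alongside.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table: zero row or column margin")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    low = bool((expected < 5).any())
    fisher_p = None
    if low:
        warnings.warn("expected counts below 5; chi-square approximation is weak")
        if obs.shape == (2, 2):
            fisher_p = float(stats.fisher_exact(obs, alternative="two-sided")[1])
    return EnrichmentResult(
        chi2=float(chi2), df=int(dof), p_value=float(p), low_expected=low, fisher_p=fisher_p
    )


@dataclass(frozen=True)
class CooccurrenceResult:
    family_a: str
    family_b: str
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    expected_both: float
    odds_ratio: float
    p_enrich: float
    p_deplete: float
    q_enrich: float = field(default=float("nan"))
    q_deplete: float = field(default=float("nan"))


def _bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, >= p elementwise)."""
    m = len(pvals)
    if m == 0:
        return pvals
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def cooccurrence(
    carriage: Mapping[str, frozenset | set],
    families: Sequence[str],
    stratum: Iterable[str] | None = None,
) -> list[CooccurrenceResult]:
    """Pairwise family co-occurrence under the fixed-margin hypergeometric null.

    ``carriage`` maps genome_id -> set of families present.  For each pair,
    a 2x2 genome contingency is built over the stratum; one-sided p-values
    are P[X >= both] (enrichment) and P[X <= both] (depletion) for
    X ~ Hypergeom(N, n_a, n_b); BH q-values are computed separately per
    direction across all tested pairs.  Families absent from the stratum
    are skipped.
    """
    ids = sorted(stratum) if stratum is not None else sorted(carriage)
    if len(ids) == 0:
        raise ValueError("empty stratum")
    sets = {f: {g for g in ids if f in carriage.get(g, frozenset())} for f in families}
    n_total = len(ids)
    prelim = []
    for fa, fb in combinations(families, 2):
        a, b = sets[fa], sets[fb]
        if not a or not b:
            continue  # family absent from stratum
        both = len(a & b)
        na, nb = len(a), len(b)
        rv = stats.hypergeom(n_total, na, nb)
        p_enr = float(rv.sf(both - 1))
        p_dep = float(rv.cdf(both))
        a_only, b_only = na - both, nb - both
        neither = n_total - na - nb + both
        if a_only * b_only > 0:
            odds = (both * neither) / (a_only * b_only)
        else:
            odds = math.inf if both * neither > 0 else float("nan")
        prelim.append(
            CooccurrenceResult(
                family_a=fa,
                family_b=fb,
                n_both=both,
                n_a_only=a_only,
                n_b_only=b_only,
                n_neither=neither,
                expected_both=na * nb / n_total,
                odds_ratio=odds,
                p_enrich=p_enr,
                p_deplete=p_dep,
            )
        )
    if not prelim:
        return []
    q_enr = _bh(np.array([r.p_enrich for r in prelim]))
    q_dep = np.array(_bh(np.array([r.p_deplete for r in prelim])))
    out = []
    for r, qe, qd in zip(prelim, q_enr, q_dep):
        out.append(
            CooccurrenceResult(
                **{**r.__dict__, "q_enrich": float(qe), "q_deplete": float(qd)}
            )
        )
    return out


def euler_counts(
    carriage: Mapping[str, frozenset | set],
    families: Sequence[str],
    stratum: Iterable[str] | None = None,
) -> dict[tuple[str, ...], int]:
    """Exclusive intersection counts for up to four chosen families.

    Each genome carrying at least one of the families contributes to
    exactly one region (the exact subset it carries), so the counts sum to
    the number of genomes carrying any of the chosen families.
    """
    if not 1 <= len(families) <= 4:
        raise ValueError("euler_counts supports 1-4 families")
    ids = stratum if stratum is not None else carriage.keys()
    counts: dict[tuple[str, ...], int] = {}
    for g in ids:
        present = tuple(f for f in families if f in carriage.get(g, frozenset()))
        if present:
            counts[present] = counts.get(present, 0) + 1
    return counts


def cooccurrence_to_frame(results: Sequence[CooccurrenceResult]) -> pd.DataFrame:
    cols = [
        "family_a", "family_b", "n_both", "n_a_only", "n_b_only", "n_neither",
        "expected_both", "odds_ratio", "p_enrich", "p_deplete", "q_enrich", "q_deplete",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
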