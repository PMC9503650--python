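"""Profile-based domain detection with empirical E-values and iterative inclusion.

A :class:`Profile` is a position-specific scoring matrix over the 20-letter
amino-acid alphabet, built from an ungapped view of a seed alignment
(columns with more than 50% gaps are discarded).  Scanning is an ungapped
sliding-window maximum of summed log-odds — a deliberately simple surrogate
for gapped local profile search that preserves the statistics being tested.
Significance is empirical: the null distribution of window maxima is
estimated from shuffled-composition decoy sequences, giving an E-value
(expected decoy hits at or above a score in a database of the same size).

``iterative_search`` implements profile-inclusion iteration: proteins whose
best hit reaches the inclusion E-value (default 0.01) are added, their
matched segments augment the alignment, the profile is rebuilt and
recalibrated, and scanning repeats until the included set is stable.  The
included set only ever grows, which guarantees termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .dataset_io import AA_ALPHABET, Collection, ProteinRecord

#: Background amino-acid frequencies (Robinson & Robinson database
#: composition), ordered as AA_ALPHABET.  Fixed so that E-value calibration
#: is stable across collections.
BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_X_INDEX = 20  # unknown residue: scores as background (log-odds 0)

NO_HIT_SCORE = -np.inf


def encode_sequence(seq: str) -> np.ndarray:
    """Map a protein sequence to integer indices; X (or anything odd) -> 20."""
    return np.array([_AA_INDEX.get(c, _X_INDEX) for c in seq], dtype=np.int64)


@dataclass
class Profile:
    family_id: str
    emission_probs: np.ndarray  # (length, 20), rows sum to 1
    background: np.ndarray  # (20,)
    pseudocount_weight: float
    log_odds: np.ndarray = field(init=False)  # (length, 21), half-bits; X column 0
    match_rows: list[str] = field(default_factory=list)  # ungapped match-column rows

    def __post_init__(self):
        with np.errstate(divide="ignore"):
            lo = 2.0 * np.log2(self.emission_probs / self.background[None, :])
        self.log_odds = np.concatenate([lo, np.zeros((lo.shape[0], 1))], axis=1)
        # finite scoring copy for the kernel: a zero-emission residue gets a
        # large finite penalty instead of -inf
        self._scan_matrix = np.nan_to_num(
            self.log_odds, neginf=-1.0e4, posinf=1.0e4
        ).astype(np.float32)

    @property
    def length(self) -> int:
        return self.emission_probs.shape[0]

    def consensus(self) -> str:
        idx = np.argmax(self.emission_probs, axis=1)
        return "".join(AA_ALPHABET[i] for i in idx)


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    family_id: str
    ali_start: int  # 1-based inclusive on the protein
    ali_end: int
    score: float  # half-bits
    e_value: float
    iteration: int


def read_seed_alignment(path) -> list[str]:
    """Read an aligned FASTA seed alignment as a list of row strings."""
    from Bio import SeqIO

    rows = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"empty seed alignment: {path}")
    return rows


def match_columns(aligned_seqs: Sequence[str], max_gap_frac: float = 0.5) -> list[str]:
    """Project aligned rows onto match columns (gap fraction <= max_gap_frac)."""
    if not aligned_seqs:
        raise ValueError("empty alignment")
    ncol = len(aligned_seqs[0])
    if any(len(s) != ncol for s in aligned_seqs):
        raise ValueError("alignment rows have unequal lengths")
    cols = []
    n = len(aligned_seqs)
    for j in range(ncol):
        gaps = sum(1 for s in aligned_seqs if s[j] in "-.")
        if gaps / n <= max_gap_frac:
            cols.append(j)
    if not cols:
        raise ValueError("alignment has no match columns")
    return ["".join(s[j] for j in cols) for s in aligned_seqs]


def build_profile(
    aligned_seqs: Sequence[str],
    pseudocount_weight: float = 0.5,
    family_id: str = "profile",
    background: np.ndarray | None = None,
) -> Profile:
    """Build a PSSM from an alignment with background pseudocounts.

    Per match column: emission = (counts + w * background) / (n_obs + w),
    where n_obs counts non-gap residues in that column and sequences carry
    uniform weight.  An X residue contributes a background-distributed
    fractional count.
    """
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)
    rows = match_columns([s.upper() for s in aligned_seqs])
    length = len(rows[0])
    counts = np.zeros((length, 20))
    n_obs = np.zeros(length)
    for row in rows:
        for j, c in enumerate(row):
            if c in "-.":
                continue
            i = _AA_INDEX.get(c)
            if i is None:
                counts[j] += bg  # X / non-standard: background-shaped count
            else:
                counts[j, i] += 1.0
            n_obs[j] += 1.0
    emission = (counts + pseudocount_weight * bg[None, :]) / (
        n_obs[:, None] + pseudocount_weight
    )
    return Profile(
        family_id=family_id,
        emission_probs=emission,
        background=bg,
        pseudocount_weight=pseudocount_weight,
        match_rows=rows,
    )


def _window_scores(log_odds: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Summed log-odds for every window; idx is (batch, seq_len) int array."""
    batch, n = idx.shape
    length = log_odds.shape[0]
    n_off = n - length + 1
    scores = np.zeros((batch, n_off))
    for i in range(length):
        scores += log_odds[i, idx[:, i : i + n_off]]
    return scores


@njit(cache=True)
def _best_windows(scan_matrix, idx):  # pragma: no cover - exercised via wrappers
    """Per-row best window sum and its offset; idx is (batch, seq_len) int8."""
    batch, n = idx.shape
    length = scan_matrix.shape[0]
    n_off = n - length + 1
    best = np.empty(batch, np.float64)
    arg = np.empty(batch, np.int64)
    for d in range(batch):
        b = -np.inf
        a = 0
        for o in range(n_off):
            s = 0.0
            for i in range(length):
                s += scan_matrix[i, idx[d, o + i]]
            if s > b:
                b = s
                a = o
        best[d] = b
        arg[d] = a
    return best, arg


def scan_protein(profile: Profile, sequence: str) -> tuple[float, int | None]:
    """Best ungapped window score (half-bits) and its 1-based start position.

    Proteins shorter than the profile return ``(-inf, None)``.  Ties go to
    the smallest start.
    """
    if len(sequence) < profile.length:
        return NO_HIT_SCORE, None
    idx = encode_sequence(sequence).astype(np.int8)[None, :]
    best, arg = _best_windows(profile._scan_matrix, idx)
    return float(best[0]), int(arg[0]) + 1


@dataclass
class NullModel:
    """Empirical null of window-maximum scores over background decoys."""

    family_id: str
    decoy_scores: np.ndarray  # sorted ascending
    database_size: int

    @property
    def n_decoys(self) -> int:
        return len(self.decoy_scores)

    def e_value(self, score: float | np.ndarray) -> float | np.ndarray:
        """Expected decoy hits at or above `score` in a database of this size.

        Uses add-one smoothing, so E is always positive: scores above every
        decoy get E = database_size / (n_decoys + 1).
        """
        n = self.n_decoys
        count_ge = n - np.searchsorted(self.decoy_scores, score, side="left")
        e = self.database_size * (count_ge + 1.0) / (n + 1.0)
        if np.ndim(score) == 0:
            return float(e)
        return e


def sample_decoys(
    rng: np.random.Generator,
    n_decoys: int,
    decoy_length: int,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Draw i.i.d. background-composition decoy sequences as an index matrix."""
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)
    cum = np.cumsum(bg / bg.sum())
    return np.searchsorted(cum, rng.random((n_decoys, decoy_length))).astype(np.int8)


def calibrate_null(
    profile: Profile,
    database_size: int,
    n_decoys: int = 1000,
    decoy_length: int = 250,
    seed: int | np.random.Generator = 0,
) -> NullModel:
    """Estimate the null score distribution from background decoys.

    Note that the add-one smoothing puts a floor of
    ``database_size / (n_decoys + 1)`` on reportable E-values, so detecting
    hits at an inclusion threshold E requires roughly
    ``database_size / E`` decoys.
    """
    if n_decoys < 100:
        raise ValueError("n_decoys must be >= 100 for a usable null")
    decoy_length = max(decoy_length, profile.length)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maxima = np.empty(n_decoys)
    chunk = 200_000
    done = 0
    while done < n_decoys:
        m = min(chunk, n_decoys - done)
        decoys = sample_decoys(rng, m, decoy_length, profile.background)
        maxima[done : done + m] = _best_windows(profile._scan_matrix, decoys)[0]
        done += m
    return NullModel(
        family_id=profile.family_id,
        decoy_scores=np.sort(maxima),
        database_size=database_size,
    )


@dataclass
class SearchResult:
    family_id: str
    hits: list[DomainHit]
    candidates: list[DomainHit]  # borderline: inclusion_E < E <= 10 * inclusion_E
    iterations: int
    converged: bool
    final_profile: Profile
    final_null: NullModel


def iterative_search(
    profile: Profile,
    proteins: Collection | Sequence[ProteinRecord],
    inclusion_E: float = 0.01,
    max_iter: int = 5,
    n_decoys: int | str = "auto",
    seed: int | np.random.Generator = 0,
) -> SearchResult:
    """Iterative profile search with an E-value inclusion threshold.

    Each round scans every protein with the current profile; proteins whose
    best window reaches ``e_value <= inclusion_E`` join the included set
    (recording the iteration at which they first passed), their matched
    segments are appended to the alignment with uniform weight, and the
    profile and its null are rebuilt.  Iteration stops when no protein is
    added or after ``max_iter`` rounds; in the latter case ``converged`` is
    False.  The included set never shrinks.

    ``n_decoys="auto"`` sizes the null so that its E-value floor sits
    comfortably below ``inclusion_E`` (1.2 * database_size / inclusion_E).
    """
    prot_list = list(proteins.proteins) if isinstance(proteins, Collection) else list(proteins)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    included: dict[str, DomainHit] = {}
    rows = list(profile.match_rows) or [profile.consensus()]
    current = profile
    lengths = [p.length for p in prot_list]
    decoy_length = int(np.median(lengths)) if lengths else profile.length
    db_size = max(len(prot_list), 1)
    if n_decoys == "auto":
        n_decoys = int(np.ceil(1.2 * db_size / inclusion_E))

    iterations = 0
    converged = False
    null = None
    for it in range(1, max_iter + 1):
        iterations = it
        null = calibrate_null(
            current, database_size=db_size, n_decoys=n_decoys,
            decoy_length=decoy_length, seed=rng,
        )
        new_hits = []
        for p in prot_list:
            if p.protein_id in included:
                continue
            score, start = scan_protein(current, p.sequence)
            if start is None:
                continue
            e = null.e_value(score)
            if e <= inclusion_E:
                new_hits.append(
                    DomainHit(
                        protein_id=p.protein_id,
                        family_id=profile.family_id,
                        ali_start=start,
                        ali_end=start + current.length - 1,
                        score=score,
                        e_value=e,
                        iteration=it,
                    )
                )
        if not new_hits:
            converged = True
            break
        for h in new_hits:
            included[h.protein_id] = h
        seqs = {p.protein_id: p.sequence for p in prot_list}
        for h in new_hits:
            rows.append(seqs[h.protein_id][h.ali_start - 1 : h.ali_end])
        current = build_profile(
            rows,
            pseudocount_weight=profile.pseudocount_weight,
            family_id=profile.family_id,
            background=profile.background,
        )

    # borderline candidate tier, assessed with the final profile and null
    candidates = []
    for p in prot_list:
        if p.protein_id in included:
            continue
        score, start = scan_protein(current, p.sequence)
        if start is None:
            continue
        e = null.e_value(score)
        if inclusion_E < e <= 10.0 * inclusion_E:
            candidates.append(
                DomainHit(
                    protein_id=p.protein_id,
                    family_id=profile.family_id,
                    ali_start=start,
                    ali_end=start + current.length - 1,
                    score=score,
                    e_value=e,
                    iteration=iterations,
                )
            )
    hits = sorted(included.values(), key=lambda h: (h.iteration, h.e_value, h.protein_id))
    return SearchResult(
        family_id=profile.family_id,
        hits=hits,
        candidates=sorted(candidates, key=lambda h: (h.e_value, h.protein_id)),
        iterations=iterations,
        converged=converged,
        final_profile=current,
        final_null=null,
    )


# ---------------------------------------------------------------------------
# hit table I/O

HIT_COLUMNS = ("protein_id", "family_id", "ali_start", "ali_end", "score", "e_value", "iteration")


def hits_to_frame(hits: Iterable[DomainHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "family_id": h.family_id,
                "ali_start": h.ali_start,
                "ali_end": h.ali_end,
                "score": h.score,
                "e_value": h.e_value,
                "iteration": h.iteration,
            }
            for h in hits
        ],
        columns=list(HIT_COLUMNS),
    )


def write_hits(hits: Iterable[DomainHit], path) -> None:
    hits_to_frame(hits).to_csv(
        path, sep="\t", index=False, lineterminator="\n", float_format="%.17g"
    )


def read_hits(path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        DomainHit(
            protein_id=str(r.protein_id),
            family_id=str(r.family_id),
            ali_start=int(r.ali_start),
            ali_end=int(r.ali_end),
            score=float(r.score),
            e_value=float(r.e_value),
            iteration=int(r.iteration),
        )
        for r in df.itertuples(index=False)
    ]
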