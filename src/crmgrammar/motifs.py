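"""Position weight matrices and synthetic CRM sequence design.

A synthetic cis-regulatory module (CRM) is assembled from optimized motif
instances — the best-scoring sequence under a trimmed position weight matrix
(PWM) — separated by "neutral" spacer sequences chosen to minimize inadvertent
binding sites for any known transcription factor, including sites straddling
the motif/spacer junctions.

Coordinates throughout are 0-based, half-open, on the plus strand of the
assembled sequence; antisense sites are stored as the reverse complement of
the motif instance and annotated with strand '-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BASES",
    "PWM",
    "MotifInstance",
    "SpacerSpec",
    "Site",
    "CRMDesign",
    "SiteAnnotation",
    "UNIFORM_BACKGROUND",
    "AT_RICH_BACKGROUND",
    "reverse_complement",
    "information_content",
    "trim_pwm",
    "best_sequence",
    "score_sequence",
    "max_pwm_affinity",
    "optimize_spacer",
    "assemble_crm",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Default background: uniform base composition.
UNIFORM_BACKGROUND = np.full(4, 0.25)

#: Preset matching an A/T-rich genome composition (A/T = 0.3, G/C = 0.2),
#: offered for motif-comparison style scoring; not the default.
AT_RICH_BACKGROUND = np.array([0.3, 0.2, 0.2, 0.3])

#: Pseudocount added to PWM probabilities before taking log-odds, purely for
#: numerical safety on zero entries.
LOG_ODDS_PSEUDOCOUNT = 1e-3

NEG_INF = float("-inf")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_sequence(seq: str) -> None:
    if any(b not in _BASE_INDEX for b in seq):
        raise ValueError(f"sequence contains non-ACGT characters: {seq!r}")


@dataclass(frozen=True)
class PWM:
    """A position weight matrix: per-position base probabilities.

    Parameters
    ----------
    name
        Identifier of the motif / transcription factor.
    matrix
        Array of shape (length, 4); row ``i`` gives P(A), P(C), P(G), P(T)
        at position ``i``. Each row must sum to 1.
    background
        Genomic base frequencies used for information content and log-odds.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        background = np.asarray(self.background, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if matrix.shape[0] == 0:
            raise ValueError("PWM matrix must have at least one position")
        if np.any(matrix < 0) or np.any(background < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(background.sum(), 1.0, atol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "background", background)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Log2-odds matrix with a small pseudocount on probabilities."""
        p = self.matrix + LOG_ODDS_PSEUDOCOUNT
        p = p / p.sum(axis=1, keepdims=True)
        q = self.background + LOG_ODDS_PSEUDOCOUNT
        q = q / q.sum()
        return np.log2(p / q[None, :])

    @property
    def max_score(self) -> float:
        """Best attainable log-odds score (per-position maxima summed)."""
        return float(self.log_odds.max(axis=1).sum())


@dataclass(frozen=True)
class MotifInstance:
    """A concrete motif sequence ("TFBS") extracted from a trimmed PWM."""

    tf_name: str
    sequence: str
    source_pwm: str

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpacerSpec:
    """Specification for a neutral spacer between two motif instances.

    The flanks are the motif ends adjacent to the spacer, included in the
    affinity evaluation so that binding sites straddling the junctions are
    penalized as well.
    """

    length: int
    left_flank: str = ""
    right_flank: str = ""
    avoid_pwms: tuple[PWM, ...] = ()
    score_tolerance: float = 0.5

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("spacer length must be >= 0")
        _validate_sequence(self.left_flank)
        _validate_sequence(self.right_flank)
        object.__setattr__(self, "avoid_pwms", tuple(self.avoid_pwms))


@dataclass(frozen=True)
class Site:
    """A motif site within a CRM design."""

    tf_name: str
    sequence: str
    orientation: str = "sense"

    def __post_init__(self) -> None:
        if self.orientation not in ("sense", "antisense"):
            raise ValueError("orientation must be 'sense' or 'antisense'")
        _validate_sequence(self.sequence)


@dataclass(frozen=True)
class CRMDesign:
    """An ordered arrangement of motif sites with edge-to-edge spacings.

    ``spacings[i]`` is the gap in bp between the end of site ``i`` and the
    start of site ``i+1``.
    """

    name: str
    sites: tuple[Site, ...]
    spacings: tuple[int, ...]

    def __post_init__(self) -> None:
        sites = tuple(self.sites)
        spacings = tuple(int(s) for s in self.spacings)
        if len(spacings) != max(len(sites) - 1, 0):
            raise ValueError("need exactly one spacing per adjacent site pair")
        if any(s < 0 for s in spacings):
            raise ValueError("spacings must be >= 0")
        object.__setattr__(self, "sites", sites)
        object.__setattr__(self, "spacings", spacings)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def tf_names(self) -> tuple[str, ...]:
        return tuple(s.tf_name for s in self.sites)


@dataclass(frozen=True)
class SiteAnnotation:
    """0-based half-open interval of a motif site on the assembled CRM."""

    crm_name: str
    start: int
    end: int
    tf_name: str
    strand: str


# ---------------------------------------------------------------------------
# Information content and trimming
# ---------------------------------------------------------------------------

def information_content(column: np.ndarray, background: np.ndarray | None = None) -> float:
    """Relative entropy (bits) of one PWM column versus the background.

    IC = sum_b p_b * log2(p_b / q_b), with 0*log(0) taken as 0. Always >= 0
    for normalized inputs.
    """
    p = np.asarray(column, dtype=float)
    q = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if p.shape != (4,):
        raise ValueError("column must have 4 entries (A, C, G, T)")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("column must be a normalized probability vector")
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / q[nz])))


def trim_pwm(pwm: PWM, ic_threshold: float = 0.4) -> PWM:
    """Trim uninformative flanking positions from a PWM.

    Positions are removed from each end while their information content is
    below ``ic_threshold``; trimming stops at the first position meeting the
    threshold, so interior low-IC positions are retained.
    """
    ic = np.array([information_content(col, pwm.background) for col in pwm.matrix])
    keep = np.nonzero(ic >= ic_threshold)[0]
    if keep.size == 0:
        raise ValueError(
            f"PWM {pwm.name!r}: every position is below IC threshold {ic_threshold}"
        )
    lo, hi = keep[0], keep[-1] + 1
    if lo == 0 and hi == len(pwm):
        return pwm
    return PWM(pwm.name, pwm.matrix[lo:hi], pwm.background)


# ---------------------------------------------------------------------------
# Best-fit sequences and affinity scanning
# ---------------------------------------------------------------------------

def best_sequence(pwm: PWM) -> MotifInstance:
    """The sequence maximizing total log-odds under the PWM.

    Per-position argmax; ties are broken lexicographically (A < C < G < T)
    so the result is deterministic.
    """
    # np.argmax returns the first maximum, which is the lexicographically
    # smallest base given the A,C,G,T column order.
    idx = np.argmax(pwm.log_odds, axis=1)
    seq = "".join(BASES[i] for i in idx)
    return MotifInstance(tf_name=pwm.name, sequence=seq, source_pwm=pwm.name)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.intp, count=len(seq))


def score_sequence(seq: str, pwm: PWM) -> float:
    """Log-odds score of a sequence whose length equals the PWM length."""
    if len(seq) != len(pwm):
        raise ValueError("sequence length must equal PWM length")
    lo = pwm.log_odds
    return float(lo[np.arange(len(seq)), _encode(seq)].sum())


def max_pwm_affinity(sequence: str, pwms: Sequence[PWM]) -> float:
    """Maximum log-odds match of any PWM at any offset on either strand.

    Returns -inf for an empty PWM list. Raises if the sequence is shorter
    than every PWM (no valid placement exists).
    """
    _validate_sequence(sequence)
    pwms = list(pwms)
    if not pwms:
        return NEG_INF
    if all(len(sequence) < len(p) for p in pwms):
        raise ValueError("sequence is shorter than every PWM")
    best = NEG_INF
    rc = reverse_complement(sequence)
    for pwm in pwms:
        w = len(pwm)
        if len(sequence) < w:
            continue
        lo = pwm.log_odds
        for strand_seq in (sequence, rc):
            enc = _encode(strand_seq)
            for off in range(len(strand_seq) - w + 1):
                s = float(lo[np.arange(w), enc[off : off + w]].sum())
                if s > best:
                    best = s
    return best


# ---------------------------------------------------------------------------
# Spacer optimization
# ---------------------------------------------------------------------------

def _junction_affinity(spacer: str, spec: SpacerSpec) -> float:
    context = spec.left_flank + spacer + spec.right_flank
    if not spec.avoid_pwms:
        return NEG_INF
    if all(len(context) < len(p) for p in spec.avoid_pwms):
        return NEG_INF
    return max_pwm_affinity(context, spec.avoid_pwms)


def optimize_spacer(spec: SpacerSpec, seed: int, n_restarts: int = 20) -> str:
    """Heuristically find a neutral spacer of the requested length.

    Greedy random-restart search: sample a random spacer, repeatedly apply
    the single-base substitution that most decreases the junction-inclusive
    maximum PWM affinity (strict decreases only), restart ``n_restarts``
    times and keep the overall best. Deterministic for a given seed.
    """
    if spec.length == 0:
        return ""
    rng = np.random.default_rng(seed)
    best_spacer: str | None = None
    best_score = float("inf")
    for _ in range(n_restarts):
        current = [BASES[i] for i in rng.integers(0, 4, size=spec.length)]
        score = _junction_affinity("".join(current), spec)
        improved = True
        while improved:
            improved = False
            for pos in range(spec.length):
                original = current[pos]
                best_base, best_local = original, score
                for base in BASES:
                    if base == original:
                        continue
                    current[pos] = base
                    trial = _junction_affinity("".join(current), spec)
                    if trial < best_local:
                        best_base, best_local = base, trial
                current[pos] = best_base
                if best_local < score:
                    score = best_local
                    improved = True
        if score < best_score:
            best_score = score
            best_spacer = "".join(current)
        if best_score == NEG_INF:
            break
    assert best_spacer is not None
    return best_spacer


# ---------------------------------------------------------------------------
# CRM assembly
# ---------------------------------------------------------------------------

def assemble_crm(
    design: CRMDesign, spacers: Sequence[str]
) -> tuple[str, list[SiteAnnotation]]:
    """Concatenate motif instances and spacers into the final CRM sequence.

    Antisense sites contribute the reverse complement of their motif
    instance. Returns the plus-strand sequence and one annotation interval
    per site (0-based, half-open); extracting an annotated interval and
    reverse-complementing '-' strand hits recovers each motif instance.
    """
    spacers = list(spacers)
    if len(spacers) != len(design.spacings):
        raise ValueError("need exactly one spacer per gap")
    for spacer, gap in zip(spacers, design.spacings):
        _validate_sequence(spacer)
        if len(spacer) != gap:
            raise ValueError(
                f"spacer length {len(spacer)} does not match designed gap {gap}"
            )
    parts: list[str] = []
    annotations: list[SiteAnnotation] = []
    pos = 0
    for i, site in enumerate(design.sites):
        seq = (
            site.sequence
            if site.orientation == "sense"
            else reverse_complement(site.sequence)
        )
        annotations.append(
            SiteAnnotation(
                crm_name=design.name,
                start=pos,
                end=pos + len(seq),
                tf_name=site.tf_name,
                strand="+" if site.orientation == "sense" else "-",
            )
        )
        parts.append(seq)
        pos += len(seq)
        if i < len(spacers):
            parts.append(spacers[i])
            pos += len(spacers[i])
    return "".join(parts), annotations
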