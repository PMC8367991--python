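"""Detection and typing of class-IV zinc-finger (GATA) domains.

The class-IV zinc finger is the motif ``C-X(2-4)-C-X(17-20)-C-X(2)-C``
followed by a basic (K/R-rich) region.  Subtypes are named by the spacer
lengths between consecutive cysteines: IV_a = (2,17,2), IV_b = (2,18,2),
IV_c = (2,20,2), IV_4 = (4,18,2); any other in-bounds combination is
reported as ``IV_other(s1,s2,s3)``.  Partial domains (IV_p) lack at least
one cysteine of the tetrad and are called by a position-specific scoring
profile built from complete reference domains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._util import AA_INDEX, AMINO_ACIDS

# spacer bounds of the scanner: C X{S1_MIN..S1_MAX} C X{S2_MIN..S2_MAX} C X{S3} C
S1_MIN, S1_MAX = 2, 4
S2_MIN, S2_MAX = 17, 20
S3 = 2

_NAMED_TYPES = {
    (2, 17, 2): "IV_a",
    (2, 18, 2): "IV_b",
    (2, 20, 2): "IV_c",
    (4, 18, 2): "IV_4",
}


@dataclass
class DomainHit:
    """One detected zinc-finger domain on a protein."""

    protein_id: str
    c_positions: tuple  # four Optional[int], 0-based indices of C1..C4
    spacers: Optional[tuple]  # (s1, s2, s3) or None for partial hits
    type: str
    span: tuple  # [start, end) in protein coordinates
    score: Optional[float] = None  # profile log-odds, set for IV_p calls
    terminal: Optional[str] = None  # "N" or "C"
    basic_fraction: Optional[float] = None

    @property
    def complete(self) -> bool:
        return all(p is not None for p in self.c_positions)

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


def classify_domain_type(spacers: Sequence[int]) -> str:
    """Name a complete domain by its inter-cysteine spacer triple."""
    s1, s2, s3 = spacers
    if not (S1_MIN <= s1 <= S1_MAX and S2_MIN <= s2 <= S2_MAX and s3 == S3):
        raise ValueError(f"spacers {tuple(spacers)} outside scanner bounds")
    return _NAMED_TYPES.get((s1, s2, s3), f"IV_other({s1},{s2},{s3})")


def _candidate_quadruples(protein: str):
    """All cysteine quadruples satisfying the spacing bounds.

    The residue 'X' (unknown) is never treated as a cysteine.
    """
    cpos = [i for i, a in enumerate(protein) if a == "C"]
    out = []
    for i1, c1 in enumerate(cpos):
        for c2 in cpos[i1 + 1:]:
            s1 = c2 - c1 - 1
            if s1 > S1_MAX:
                break
            if s1 < S1_MIN:
                continue
            for c3 in cpos:
                if c3 <= c2:
                    continue
                s2 = c3 - c2 - 1
                if s2 > S2_MAX:
                    break
                if s2 < S2_MIN:
                    continue
                c4 = c3 + S3 + 1
                if c4 < len(protein) and protein[c4] == "C":
                    out.append((c1, c2, c3, c4))
    return out


def _normalize_protein(protein: str) -> str:
    if not protein:
        raise ValueError("empty protein sequence")
    if protein != protein.upper():
        warnings.warn("lowercase residues normalized to uppercase")
        protein = protein.upper()
    return protein


def scan_zf_motifs(protein: str, protein_id: str = "") -> list[DomainHit]:
    """Find all complete class-IV zinc-finger motifs in a protein.

    Overlapping candidate quadruples are resolved deterministically:
    leftmost C1 first, then smallest s1, then smallest s2.  Accepted hits
    never overlap; the result is sorted by start position.
    """
    protein = _normalize_protein(protein)
    cands = _candidate_quadruples(protein)
    # leftmost-first, then shortest s1, then shortest s2
    cands.sort(key=lambda q: (q[0], q[1] - q[0], q[2] - q[1]))
    accepted: list[tuple] = []
    for q in cands:
        if all(q[0] > a[3] or q[3] < a[0] for a in accepted):
            accepted.append(q)
    accepted.sort(key=lambda q: q[0])
    hits = []
    for c1, c2, c3, c4 in accepted:
        spacers = (c2 - c1 - 1, c3 - c2 - 1, c4 - c3 - 1)
        hits.append(
            DomainHit(
                protein_id=protein_id,
                c_positions=(c1, c2, c3, c4),
                spacers=spacers,
                type=classify_domain_type(spacers),
                span=(c1, c4 + 1),
            )
        )
    return hits


def terminal_class(hit: DomainHit, protein_length: int, threshold: float = 0.5) -> str:
    """Half of the protein the domain sits in: 'N' or 'C'.

    Subfamily IV domains are N-terminal, subfamilies I-III C-terminal; the
    midpoint-fraction rule with a strict ``<`` sends an exact tie to 'C'.
    """
    if protein_length <= 0:
        raise ValueError("zero-length protein")
    if protein_length < hit.end:
        raise ValueError("hit extends beyond protein")
    midpoint = (hit.start + hit.end) / 2.0
    return "N" if midpoint / protein_length < threshold else "C"


def basic_region_fraction(protein: str, hit: DomainHit, window: int = 15) -> Optional[float]:
    """Fraction of K/R in the ``window`` residues downstream of C4.

    Annotation only — family membership never filters on it.  Returns None
    when no residues follow the domain.
    """
    downstream = protein[hit.end: hit.end + window]
    if not downstream:
        return None
    return sum(1 for a in downstream if a in "KR") / len(downstream)


def annotate_hit(protein: str, hit: DomainHit, window: int = 15) -> DomainHit:
    """Fill the terminal class and basic-region fraction in place."""
    hit.terminal = terminal_class(hit, len(protein))
    hit.basic_fraction = basic_region_fraction(protein, hit, window)
    return hit


# ---------------------------------------------------------------------------
# profile (PSSM) scoring for partial domains


@dataclass
class DomainProfile:
    """Log-odds profile over aligned complete domains.

    Columns score ``log(p_col(residue) / p_background(residue))`` with a
    Laplace pseudocount; 'X' scores the background-expected column score.
    """

    length: int
    log_odds: np.ndarray  # (length, 20)
    background: np.ndarray  # (20,)
    threshold: float
    anchor_offsets: tuple = ()  # column indices expected to hold the C tetrad
    x_scores: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.x_scores is None:
            self.x_scores = self.log_odds @ self.background

    def score(self, window: str) -> float:
        """Score one window of length ``self.length``."""
        if len(window) != self.length:
            raise ValueError("window length mismatch")
        total = 0.0
        for j, a in enumerate(window):
            i = AA_INDEX.get(a)
            total += self.x_scores[j] if i is None else self.log_odds[j, i]
        return float(total)


def build_profile(
    reference_domains: Sequence[str],
    pseudocount: float = 1.0,
    margin: float = 10.0,
    anchor_offsets: Sequence[int] = (),
) -> DomainProfile:
    """Build a log-odds profile from >=5 equal-length aligned domains.

    All-gap columns are dropped with a warning.  The calling threshold
    defaults to the minimum self-score of the references minus ``margin``.
    """
    if len(reference_domains) < 5:
        raise ValueError("need at least 5 reference domains")
    L = len(reference_domains[0])
    if any(len(r) != L for r in reference_domains):
        raise ValueError("reference domains must share one aligned length")
    refs = [r.upper() for r in reference_domains]
    gapchars = {"-", "."}
    keep = [
        j for j in range(L) if any(r[j] not in gapchars for r in refs)
    ]
    if len(keep) < L:
        warnings.warn(f"dropped {L - len(keep)} all-gap column(s)")

    n_aa = len(AMINO_ACIDS)
    counts = np.zeros((len(keep), n_aa))
    for r in refs:
        for jj, j in enumerate(keep):
            i = AA_INDEX.get(r[j])
            if i is not None:
                counts[jj, i] += 1
    bg = counts.sum(axis=0) + pseudocount
    bg /= bg.sum()
    col = counts + pseudocount
    col /= col.sum(axis=1, keepdims=True)
    log_odds = np.log(col) - np.log(bg)

    prof = DomainProfile(
        length=len(keep),
        log_odds=log_odds,
        background=bg,
        threshold=0.0,
        anchor_offsets=tuple(anchor_offsets),
    )
    degapped = ["".join(r[j] for j in keep) for r in refs]
    self_scores = [prof.score(d.replace("-", "X").replace(".", "X")) for d in degapped]
    prof.threshold = min(self_scores) - margin
    return prof


def scan_partial(
    protein: str, profile: DomainProfile, protein_id: str = ""
) -> list[DomainHit]:
    """Call partial (IV_p) domains: profile score above threshold with an
    incomplete cysteine tetrad.  Windows containing a complete motif are
    suppressed — the complete call wins.  Overlapping qualifying windows
    are merged, keeping the best-scoring one.
    """
    protein = _normalize_protein(protein)
    complete = scan_zf_motifs(protein, protein_id)
    spans = [h.span for h in complete]
    L = profile.length
    raw: list[DomainHit] = []
    for start in range(0, len(protein) - L + 1):
        window = protein[start: start + L]
        s = profile.score(window)
        if s < profile.threshold:
            continue
        end = start + L
        if any(start < ce and cs < end for cs, ce in spans):
            continue
        cpos = tuple(
            start + off if window[off] == "C" else None
            for off in profile.anchor_offsets
        ) or (None, None, None, None)
        if all(p is not None for p in cpos):
            continue  # complete tetrad at the anchors: not a partial call
        raw.append(
            DomainHit(
                protein_id=protein_id,
                c_positions=cpos,
                spacers=None,
                type="IV_p",
                span=(start, end),
                score=s,
            )
        )
    raw.sort(key=lambda h: (-h.score, h.start))
    kept: list[DomainHit] = []
    for h in raw:
        if all(h.start >= k.end or h.end <= k.start for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def scan_all(
    protein: str, protein_id: str = "", profile: Optional[DomainProfile] = None
) -> list[DomainHit]:
    """Complete hits plus, when a profile is given, IV_p calls; annotated."""
    hits = scan_zf_motifs(protein, protein_id)
    if profile is not None:
        hits += scan_partial(protein, profile, protein_id)
    hits.sort(key=lambda h: h.start)
    return [annotate_hit(protein, h) for h in hits]


def best_hit(hits: Iterable[DomainHit]) -> Optional[DomainHit]:
    """Representative domain of a protein: complete hits beat IV_p, then
    higher profile score, then leftmost."""
    hits = list(hits)
    if not hits:
        return None
    return min(
        hits,
        key=lambda h: (not h.complete, -(h.score if h.score is not None else math.inf), h.start),
    )


def hits_table(hits: Iterable[DomainHit]):
    """Tabulate hits as a DataFrame mirroring the TSV output columns."""
    import pandas as pd

    rows = []
    for h in hits:
        s1, s2, s3 = h.spacers if h.spacers else (None, None, None)
        rows.append(
            {
                "protein_id": h.protein_id,
                "start": h.start,
                "end": h.end,
                "s1": s1,
                "s2": s2,
                "s3": s3,
                "type": h.type,
                "score": h.score,
                "terminal": h.terminal,
                "basic_fraction": h.basic_fraction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "start", "end", "s1", "s2", "s3",
            "type", "score", "terminal", "basic_fraction",
        ],
    )
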