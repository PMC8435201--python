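"""Hybridization-capture bait design: cleaning, tiling, and specificity filters.

The workflow mirrors how capture probes are built from a curated set of
repeat-masked nucleotide reference sequences:

1. :func:`clean_sequence` — short runs of ambiguous bases (N) are replaced
   with T repeats and short fragments are right-padded with T so a full
   120-mer can always be placed.
2. :func:`tile_baits` — 120-mers tiled every 50 bp (about 2.4x nominal
   density); candidates with residual N or too much soft-masked (lowercase)
   sequence are rejected immediately.
3. :func:`filter_hits` — alignment hits of each candidate against reference
   genomes are kept only when strictly longer than 45 bp and strictly more
   than 75% identical.
4. :func:`specificity_filter` — a candidate survives only with a moderate
   off-target profile: at most 10 retained hits with melting temperature in
   62.5-65 degC, at most 2 above 65 degC, plus a pluggable flanking-region
   criterion.

BLAST / RepeatMasker themselves are out of scope: masked FASTA and hit
tables are inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

DEFAULT_BAIT_LENGTH = 120
DEFAULT_SPACING = 50
DEFAULT_MAX_N_RUN = 10
DEFAULT_MIN_HIT_LENGTH = 45
DEFAULT_MIN_HIT_IDENTITY = 75.0
DEFAULT_MID_TM_RANGE = (62.5, 65.0)
DEFAULT_MAX_MID_TM_HITS = 10
DEFAULT_MAX_HIGH_TM_HITS = 2
DEFAULT_MAX_MASKED_FRACTION = 0.25


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit of a bait candidate against a reference target."""

    bait_id: str
    target_id: str
    length: int
    identity: float  # percent
    tm: float | None = None  # degrees C; estimated if absent

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("hit length must be >= 1")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("percent identity must be in [0, 100]")


@dataclass(frozen=True)
class BaitCandidate:
    """A tiled probe with provenance, mask content, and filter status."""

    bait_id: str
    source_id: str
    start: int  # 0-based on the cleaned source sequence
    sequence: str
    status: str = "candidate"  # candidate | retained | rejected:<reason>

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start must be non-negative")
        if not self.sequence:
            raise ValueError("empty bait sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def masked_fraction(self) -> float:
        return sum(1 for b in self.sequence if b.islower()) / len(self.sequence)

    @property
    def rejected(self) -> bool:
        return self.status.startswith("rejected")


def clean_sequence(
    seq: str,
    max_n_run: int = DEFAULT_MAX_N_RUN,
    pad_to: int = DEFAULT_BAIT_LENGTH,
) -> str:
    """Replace short N-runs with T-runs and pad short fragments with T.

    Maximal runs of N (case-insensitive) no longer than ``max_n_run`` are
    replaced by T repeats of equal length; longer runs stay untouched.
    Sequences shorter than ``pad_to`` are right-padded with T.  Idempotent.
    """
    if not seq:
        raise ValueError("empty sequence")

    def _sub(match: re.Match) -> str:
        run = match.group(0)
        return "T" * len(run) if len(run) <= max_n_run else run

    cleaned = re.sub(r"[Nn]+", _sub, seq)
    if len(cleaned) < pad_to:
        cleaned += "T" * (pad_to - len(cleaned))
    return cleaned


def tile_baits(
    seq: str,
    source_id: str = "seq",
    bait_length: int = DEFAULT_BAIT_LENGTH,
    spacing: int = DEFAULT_SPACING,
    max_masked_fraction: float = DEFAULT_MAX_MASKED_FRACTION,
) -> list[BaitCandidate]:
    """Tile candidates at starts 0, spacing, 2*spacing, ... while a full
    bait fits; flag over-masked or still-ambiguous candidates as rejected.

    The sequence must already be cleaned/padded to at least one bait length
    (floor((L - bait_length)/spacing) + 1 candidates result).
    """
    if len(seq) < bait_length:
        raise ValueError(
            f"sequence of {len(seq)} bp is shorter than a {bait_length} bp "
            "bait; run clean_sequence first"
        )
    candidates = []
    for i, start in enumerate(range(0, len(seq) - bait_length + 1, spacing)):
        window = seq[start:start + bait_length]
        cand = BaitCandidate(
            bait_id=f"{source_id}_b{i + 1}",
            source_id=source_id,
            start=start,
            sequence=window,
        )
        if "N" in window.upper():
            cand = replace(cand, status="rejected:ambiguous")
        elif cand.masked_fraction > max_masked_fraction:
            cand = replace(cand, status="rejected:masked")
        candidates.append(cand)
    return candidates


def filter_hits(
    hits: Iterable[HitRecord],
    min_length: int = DEFAULT_MIN_HIT_LENGTH,
    min_identity: float = DEFAULT_MIN_HIT_IDENTITY,
) -> list[HitRecord]:
    """Keep hits strictly longer than ``min_length`` bp AND strictly above
    ``min_identity`` percent identity (both bounds excluded)."""
    return [h for h in hits if h.length > min_length and h.identity > min_identity]


def estimate_tm(
    hit: HitRecord,
    gc_fraction: float = 0.5,
    sodium_molar: float = 0.9,
    mismatch_penalty: float = 1.0,
) -> float:
    """Duplex melting temperature (degC) of a hit's matched span.

    A salt-adjusted GC/length approximation with a per-percent-mismatch
    penalty:

        Tm = 81.5 + 16.6*log10([Na+]) + 0.41*(%GC) - 600/length
             - penalty * (100 - %identity)

    The defaults approximate stringent in-solution hybridization buffer
    conditions; every coefficient is a parameter so alternative models can
    be swapped in.  Deterministic.
    """
    if hit.length < 1:
        raise ValueError("hit length must be >= 1")
    import math

    return (
        81.5
        + 16.6 * math.log10(sodium_molar)
        + 0.41 * (100.0 * gc_fraction)
        - 600.0 / hit.length
        - mismatch_penalty * (100.0 - hit.identity)
    )


def annotate_tm(hits: Sequence[HitRecord], **tm_params) -> list[HitRecord]:
    """Fill in Tm for hits lacking one, via :func:`estimate_tm`."""
    return [
        h if h.tm is not None else replace(h, tm=estimate_tm(h, **tm_params))
        for h in hits
    ]


FlankPredicate = Callable[[BaitCandidate, Sequence[HitRecord]], bool]


def _flank_pass_through(candidate: BaitCandidate, hits: Sequence[HitRecord]) -> bool:
    # The published flanking-region wording is ambiguous; the default
    # predicate accepts everything so the two unambiguous Tm-count rules
    # decide, and callers can plug in their own interpretation.
    return True


def specificity_filter(
    candidate: BaitCandidate,
    hits: Sequence[HitRecord],
    mid_tm_range: tuple[float, float] = DEFAULT_MID_TM_RANGE,
    max_mid_tm_hits: int = DEFAULT_MAX_MID_TM_HITS,
    max_high_tm_hits: int = DEFAULT_MAX_HIGH_TM_HITS,
    flank_predicate: FlankPredicate = _flank_pass_through,
) -> BaitCandidate:
    """Tm-binned specificity rule: retain iff the candidate has at most
    ``max_mid_tm_hits`` hits with Tm inside ``mid_tm_range`` (inclusive),
    at most ``max_high_tm_hits`` hits above its upper bound, and passes the
    flanking predicate.  Already-rejected candidates pass through
    unchanged, keeping one primary rejection reason per bait."""
    if candidate.rejected:
        return candidate
    lo, hi = mid_tm_range
    tms = []
    for h in hits:
        if h.tm is None:
            raise ValueError(f"hit {h.bait_id}->{h.target_id} lacks a Tm; "
                             "run annotate_tm first")
        tms.append(h.tm)
    mid = sum(1 for t in tms if lo <= t <= hi)
    high = sum(1 for t in tms if t > hi)
    if mid > max_mid_tm_hits:
        return replace(candidate, status="rejected:mid-bin")
    if high > max_high_tm_hits:
        return replace(candidate, status="rejected:high-bin")
    if not flank_predicate(candidate, hits):
        return replace(candidate, status="rejected:flank")
    return replace(candidate, status="retained")


def design_baits(
    sequences: dict[str, str],
    hits: Sequence[HitRecord],
    bait_length: int = DEFAULT_BAIT_LENGTH,
    spacing: int = DEFAULT_SPACING,
    max_n_run: int = DEFAULT_MAX_N_RUN,
    max_masked_fraction: float = DEFAULT_MAX_MASKED_FRACTION,
    min_hit_length: int = DEFAULT_MIN_HIT_LENGTH,
    min_hit_identity: float = DEFAULT_MIN_HIT_IDENTITY,
    mid_tm_range: tuple[float, float] = DEFAULT_MID_TM_RANGE,
    max_mid_tm_hits: int = DEFAULT_MAX_MID_TM_HITS,
    max_high_tm_hits: int = DEFAULT_MAX_HIGH_TM_HITS,
    flank_predicate: FlankPredicate = _flank_pass_through,
) -> list[BaitCandidate]:
    """End-to-end deterministic pipeline: clean, tile, filter, decide.

    ``hits`` are keyed to candidates by bait id (``<source>_b<k>``).
    Every candidate comes back with a final status and exactly one primary
    rejection reason if rejected.
    """
    usable = filter_hits(annotate_tm(hits), min_hit_length, min_hit_identity)
    by_bait: dict[str, list[HitRecord]] = {}
    for h in usable:
        by_bait.setdefault(h.bait_id, []).append(h)

    decided = []
    for source_id in sequences:
        cleaned = clean_sequence(sequences[source_id], max_n_run, bait_length)
        for cand in tile_baits(
            cleaned, source_id, bait_length, spacing, max_masked_fraction
        ):
            decided.append(
                specificity_filter(
                    cand,
                    by_bait.get(cand.bait_id, []),
                    mid_tm_range,
                    max_mid_tm_hits,
                    max_high_tm_hits,
                    flank_predicate,
                )
            )
    return decided


def read_hit_table(path) -> list[HitRecord]:
    """Read a TSV hit table: bait_id, target_id, length, identity[, tm]."""
    from pathlib import Path

    hits = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (4, 5):
            raise ValueError(f"line {lineno}: expected 4 or 5 tab-separated fields")
        tm = float(fields[4]) if len(fields) == 5 and fields[4] != "" else None
        hits.append(
            HitRecord(fields[0], fields[1], int(fields[2]), float(fields[3]), tm)
        )
    return hits


def write_bait_table(candidates: Sequence[BaitCandidate], path) -> None:
    """Write the decision table: one candidate per row, stable order."""
    with open(path, "w") as fh:
        fh.write("bait_id\tsource_id\tstart\tlength\tmasked_fraction\tstatus\n")
        for c in candidates:
            fh.write(
                f"{c.bait_id}\t{c.source_id}\t{c.start}\t{c.length}\t"
                f"{c.masked_fraction:.6g}\t{c.status}\n"
            )


__all__ = [
    "BaitCandidate",
    "HitRecord",
    "clean_sequence",
    "tile_baits",
    "filter_hits",
    "estimate_tm",
    "annotate_tm",
    "specificity_filter",
    "design_baits",
    "read_hit_table",
    "write_bait_table",
]
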