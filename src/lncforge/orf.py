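"""Longest open reading frame detection.

An ORF here is a *complete* reading frame: an ATG start codon through the
last sense codon before an in-frame stop (TAA/TAG/TGA).  The amino-acid
length counts the initial Met but not the stop.  Coding-potential filters
compare this length, and the fraction of the transcript the ORF covers
(stop codon included), against their cutoffs.

Codons containing N are never accepted as start or stop codons, so
ambiguous bases cannot fabricate or terminate an ORF.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import reverse_complement

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


@dataclass(frozen=True)
class OrfResult:
    """Longest complete ORF of a transcript sequence.

    ``nt_span`` is [start, end) within the scanned sequence (the reverse
    complement when ``on_reverse``), and includes the stop codon.
    ``fraction`` = 3*(aa_length + 1) / sequence length: the ORF footprint,
    stop codon included, as a fraction of the transcript.
    """

    aa_length: int
    frame: int = 0
    on_reverse: bool = False
    nt_span: tuple[int, int] = (0, 0)
    fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.aa_length < 0:
            raise ValueError("aa_length must be >= 0")


def _scan_forward(seq: str):
    """Yield (aa_length, start, end) for every maximal complete ORF.

    Within a frame, the first ATG after the previous stop opens the ORF
    that the next in-frame stop closes; later ATGs before the same stop
    give strictly shorter ORFs and are irrelevant for the maximum.
    """
    n = len(seq)
    for frame in range(3):
        open_start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if open_start is None:
                if codon == START_CODON:
                    open_start = i
            elif codon in STOP_CODONS:
                yield (i - open_start) // 3, open_start, i + 3, frame
                open_start = None


def find_longest_orf(sequence: str, frames: int = 3) -> OrfResult:
    """Longest complete ORF over 3 forward frames, or 6 when ``frames=6``.

    Ties are broken by the smallest start position in the scanned
    sequence, then by preferring the forward strand.  An empty sequence or
    one with no complete ORF yields ``aa_length == 0``.
    """
    if frames not in (3, 6):
        raise ValueError("frames must be 3 or 6")
    sequence = sequence.upper()
    n = len(sequence)
    candidates = []
    for aa, start, end, frame in _scan_forward(sequence):
        candidates.append((aa, start, False, frame, end))
    if frames == 6:
        for aa, start, end, frame in _scan_forward(reverse_complement(sequence)):
            candidates.append((aa, start, True, frame, end))
    if not candidates:
        return OrfResult(aa_length=0)
    aa, start, on_rev, frame, end = min(
        candidates, key=lambda c: (-c[0], c[1], c[2])
    )
    return OrfResult(
        aa_length=aa,
        frame=frame,
        on_reverse=on_rev,
        nt_span=(start, end),
        fraction=(3 * (aa + 1)) / n if n else 0.0,
    )
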