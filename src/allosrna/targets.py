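"""miRNA target prediction by ungapped complementarity scoring.

A simplified psRNATarget-style expectation score: each transcript window the
length of the miRNA is compared with the miRNA read 3'->5' (i.e. the window is
matched against the miRNA's reverse complement). Per-position penalties are 0
for a Watson-Crick pair, 0.5 for a G:U wobble and 1 for a mismatch; penalties
at miRNA positions 2-13 (5' end, 1-based — the seed-critical region) are
doubled. Lower expectation = better site; windows at or under the cutoff
(default 5.0) are reported.

This scorer is a deliberately simplified stand-in for the full psRNATarget
algorithm: no bulges/gaps and no target-accessibility term.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

WOBBLE = {("G", "T"), ("T", "G")}   # G:U pairs, DNA alphabet
WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
SEED_START, SEED_END = 2, 13        # 1-based miRNA positions with doubled penalty
DEFAULT_CUTOFF = 5.0


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int              # 0-based half-open site interval on the transcript
    end: int
    expectation: float
    alignment: str          # per position: '|' pair, 'o' wobble, 'x' mismatch


def _pair_symbols(mirna: str, site: str) -> tuple[float, str]:
    length = len(mirna)
    total = 0.0
    symbols = []
    for j in range(length):  # j: 0-based position from the miRNA 5' end
        m = mirna[j]
        t = site[length - 1 - j]
        if (m, t) in WC:
            penalty, sym = 0.0, "|"
        elif (m, t) in WOBBLE:
            penalty, sym = 0.5, "o"
        else:
            penalty, sym = 1.0, "x"
        if SEED_START <= j + 1 <= SEED_END:
            penalty *= 2.0
        total += penalty
        symbols.append(sym)
    # alignment string reported 5'->3' along the transcript site
    return total, "".join(reversed(symbols))


def score_site(mirna: str, site: str) -> float:
    """Expectation penalty of one ungapped miRNA:site duplex (lower = better)."""
    mirna = mirna.upper().replace("U", "T")
    site = site.upper().replace("U", "T")
    if len(mirna) != len(site):
        raise ValueError("ungapped scoring requires equal-length miRNA and site")
    return _pair_symbols(mirna, site)[0]


_COMP = {ord("A"): ord("T"), ord("T"): ord("A"),
         ord("G"): ord("C"), ord("C"): ord("G")}


def _window_scores(mirna: str, transcript: str) -> np.ndarray:
    """Expectation for every transcript window, vectorised over windows."""
    L = len(mirna)
    n = len(transcript) - L + 1
    if n <= 0:
        return np.empty(0)
    t = np.frombuffer(transcript.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    scores = np.zeros(n)
    for j in range(L):  # miRNA position j (0-based from the 5' end)
        col = windows[:, L - 1 - j]
        mb = ord(mirna[j])
        wc = col == _COMP.get(mb, 0)
        if mirna[j] == "G":
            wobble = col == ord("T")
        elif mirna[j] == "T":
            wobble = col == ord("G")
        else:
            wobble = np.zeros(n, dtype=bool)
        penalty = np.where(wc, 0.0, np.where(wobble, 0.5, 1.0))
        if SEED_START <= j + 1 <= SEED_END:
            penalty = penalty * 2.0
        scores += penalty
    return scores


def scan_transcript(mirna_id: str, mirna: str, transcript_id: str,
                    transcript: str, cutoff: float = DEFAULT_CUTOFF) -> list[TargetHit]:
    """Score every window of the transcript; report hits with expectation <= cutoff,
    sorted by (score, position). Overlapping hits are allowed."""
    mirna = mirna.upper().replace("U", "T")
    transcript = transcript.upper().replace("U", "T")
    L = len(mirna)
    scores = _window_scores(mirna, transcript)
    hits = []
    for start in np.nonzero(scores <= cutoff)[0]:
        site = transcript[start : start + L]
        expectation, alignment = _pair_symbols(mirna, site)
        hits.append(TargetHit(mirna_id, transcript_id, int(start), int(start) + L,
                              expectation, alignment))
    return sorted(hits, key=lambda h: (h.expectation, h.start))


def predict_targets(mirnas: Mapping[str, str], transcripts: Mapping[str, str],
                    cutoff: float = DEFAULT_CUTOFF) -> list[TargetHit]:
    hits = []
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            hits.extend(scan_transcript(mid, mseq, tid, tseq, cutoff))
    return hits


def hits_to_tsv(hits: Sequence[TargetHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# simplified ungapped psRNATarget-style expectation scores\n")
        fh.write("mirna\ttranscript\tstart\tend\texpectation\talignment\n")
        for h in hits:
            fh.write(f"{h.mirna_id}\t{h.transcript_id}\t{h.start}\t{h.end}\t"
                     f"{h.expectation:g}\t{h.alignment}\n")
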