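"""PAM-anchored sgRNA binding-site enumeration and probe proximity mapping.

Exhaustively enumerates, on both strands, every genomic 20-mer whose
Hamming distance to a guide spacer is within a mismatch budget and that is
immediately followed (3') by a PAM matching an IUPAC pattern (default NGG).
Vectorised over sliding windows; by contract the result is identical to a
naive position-by-position scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GuideRNA:
    guide_id: str
    spacer: str  # 20 nt, 5'->3'
    pam_pattern: str = "NGG"

    def __post_init__(self):
        if len(self.spacer) != 20:
            raise ValueError("spacer must be 20 nt")
        if any(b not in "ACGT" for b in self.spacer):
            raise ValueError(f"spacer contains non-ACGT base: {self.spacer}")
        if any(b not in IUPAC for b in self.pam_pattern.upper()):
            raise ValueError(f"invalid IUPAC PAM pattern: {self.pam_pattern}")


@dataclass(frozen=True)
class OffTargetHit:
    guide_id: str
    chromosome: str
    start: int  # 0-based half-open protospacer interval, forward coordinates
    end: int
    strand: str
    mismatches: int
    mismatch_positions: tuple[int, ...]  # spacer-indexed, 0-based
    pam_observed: str  # as read on the guide-binding strand


@dataclass(frozen=True)
class ProximityRecord:
    guide_id: str
    probe_id: str
    distance: int
    hit: OffTargetHit


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


_LUT = np.full(256, 4, dtype=np.uint8)
for b, c in _CODE.items():
    _LUT[ord(b)] = c


def _pam_masks(pattern: str) -> np.ndarray:
    """allowed[i, code] — True when base code matches pattern position i.
    Ambiguous genome bases (code 4) never match anything."""
    allowed = np.zeros((len(pattern), 5), dtype=bool)
    for i, ch in enumerate(pattern.upper()):
        for b in IUPAC[ch]:
            allowed[i, _CODE[b]] = True
    return allowed


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def find_sites(sequences: dict[str, str], guides: list[GuideRNA],
               max_mismatch: int = 3) -> list[OffTargetHit]:
    """Enumerate all protospacer+PAM matches for every guide on both strands.

    ``sequences`` maps chromosome name to sequence. PAM bases never count
    toward the mismatch budget; an N in the genome can never match a spacer
    base or PAM base (it counts as a mismatch in the spacer and disqualifies
    the PAM).
    """
    if max_mismatch > 5:
        raise ValueError("max_mismatch must be <= 5")
    hits: list[OffTargetHit] = []
    for chrom in sorted(sequences):
        seq = sequences[chrom].upper()
        codes = _LUT[_encode(seq)]
        for guide in guides:
            hits.extend(_scan_one(chrom, seq, codes, guide, max_mismatch))
    return hits


def _scan_one(chrom, seq, codes, guide, max_mismatch):
    k = len(guide.spacer)
    plen = len(guide.pam_pattern)
    L = len(codes)
    out = []
    if L < k + plen:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    pam_allowed = _pam_masks(guide.pam_pattern)

    # forward strand: spacer at [i, i+k), PAM at [i+k, i+k+plen)
    spacer_f = _LUT[_encode(guide.spacer)]
    # an N (code 4) never equals a spacer code, so it always counts as a mismatch
    mism_f = windows[: L - k - plen + 1] != spacer_f
    nm_f = mism_f.sum(axis=1)
    pam_ok = np.ones(L - k - plen + 1, dtype=bool)
    for j in range(plen):
        pam_ok &= pam_allowed[j][codes[k + j : L - plen + 1 + j]]
    for i in np.nonzero((nm_f <= max_mismatch) & pam_ok)[0]:
        mm = tuple(int(x) for x in np.nonzero(mism_f[i])[0])
        out.append(OffTargetHit(
            guide_id=guide.guide_id, chromosome=chrom,
            start=int(i), end=int(i + k), strand="+",
            mismatches=int(nm_f[i]), mismatch_positions=mm,
            pam_observed=seq[i + k : i + k + plen]))

    # reverse strand: protospacer occupies forward [s, s+k) with the PAM at
    # forward [s-plen, s); compare the window to revcomp(spacer), with
    # spacer index j sitting at forward offset k-1-j
    spacer_r = _LUT[_encode(revcomp(guide.spacer))]
    pam_r = _pam_masks(_revcomp_pattern(guide.pam_pattern))
    starts = np.arange(plen, L - k + 1)
    mism_r = windows[plen : L - k + 1] != spacer_r
    nm_r = mism_r.sum(axis=1)
    pam_ok_r = np.ones(len(starts), dtype=bool)
    for j in range(plen):
        pam_ok_r &= pam_r[j][codes[j : j + len(starts)]]
    for idx in np.nonzero((nm_r <= max_mismatch) & pam_ok_r)[0]:
        s = int(starts[idx])
        mm = tuple(sorted(int(k - 1 - x) for x in np.nonzero(mism_r[idx])[0]))
        out.append(OffTargetHit(
            guide_id=guide.guide_id, chromosome=chrom,
            start=s, end=s + k, strand="-",
            mismatches=int(nm_r[idx]), mismatch_positions=mm,
            pam_observed=revcomp(seq[s - plen : s])))
    return out


def _revcomp_pattern(pattern: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    return "".join(comp[c] for c in pattern.upper()[::-1])


def map_hits_to_probes(hits: list[OffTargetHit], probes,
                       window: int = 1000) -> list[ProximityRecord]:
    """Keep (guide hit, probe) pairs within ``window`` bases on one chromosome.

    Distance is the minimal base separation between the probe coordinate and
    the protospacer interval: 0 when the coordinate lies inside it. The
    bound is closed (distance == window is kept).
    """
    records = []
    for hit in hits:
        for probe in probes:
            if probe.chromosome != hit.chromosome:
                continue
            if hit.start <= probe.position < hit.end:
                d = 0
            else:
                d = min(abs(probe.position - hit.start),
                        abs(probe.position - (hit.end - 1)))
            if d <= window:
                records.append(ProximityRecord(
                    guide_id=hit.guide_id, probe_id=probe.probe_id,
                    distance=int(d), hit=hit))
    return records
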