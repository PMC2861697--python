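"""Sequence-conservation scoring of bound regions.

A region's conservation score is the maximum 100 bp moving average of
per-base PhastCons-style scores inside the region.  A data-driven
threshold separating bound regions from random background sequence splits
sites into conserved and non-conserved classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_model import BindingSite

__all__ = [
    "ConservationTrack",
    "read_track",
    "region_conservation",
    "select_threshold",
    "partition_conserved",
]


@dataclass
class ConservationTrack:
    """Dense per-base conservation scores, one array per chromosome.

    ``offset[chrom]`` is the 1-based position of the first array element.
    Bases not covered by the source track score 0 (missing alignment is
    treated as unconserved).
    """

    scores: dict[str, np.ndarray]
    offset: dict[str, int]

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores for a 0-based half-open interval; uncovered bases are 0."""
        if chrom not in self.scores:
            raise KeyError(f"chromosome {chrom!r} absent from conservation track")
        arr = self.scores[chrom]
        off0 = self.offset[chrom] - 1  # 0-based start of the array
        out = np.zeros(end - start)
        lo = max(start, off0)
        hi = min(end, off0 + len(arr))
        if lo < hi:
            out[lo - start : hi - start] = arr[lo - off0 : hi - off0]
        return out


def read_track(path) -> ConservationTrack:
    """Read a bedGraph or fixed-step WIG file into a dense track.

    bedGraph intervals are 0-based half-open and must not overlap; scores
    must lie in [0, 1].  Gaps between intervals are filled with 0.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    mode = "bedgraph"
    fs_chrom, fs_pos, fs_step, fs_span = None, None, 1, 1
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "fixedstep"
                params = dict(kv.split("=") for kv in line.split()[1:])
                fs_chrom = params["chrom"]
                fs_pos = int(params["start"])  # 1-based
                fs_step = int(params.get("step", 1))
                fs_span = int(params.get("span", 1))
                continue
            if line.startswith("variableStep"):
                raise ValueError("variableStep WIG is not supported")
            fields = line.split()
            if mode == "fixedstep" and len(fields) == 1:
                value = float(fields[0])
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"{path}:{ln}: score {value} outside [0, 1]")
                start0 = fs_pos - 1
                intervals.setdefault(fs_chrom, []).append((start0, start0 + fs_span, value))
                fs_pos += fs_step
            else:
                chrom, start_s, end_s, value_s = fields[:4]
                start, end, value = int(start_s), int(end_s), float(value_s)
                if start >= end:
                    raise ValueError(f"{path}:{ln}: empty or inverted interval")
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"{path}:{ln}: score {value} outside [0, 1]")
                intervals.setdefault(chrom, []).append((start, end, value))

    scores: dict[str, np.ndarray] = {}
    offset: dict[str, int] = {}
    for chrom, ivs in intervals.items():
        ivs.sort()
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping track intervals on {chrom} at {s1}")
        lo = ivs[0][0]
        hi = max(e for _, e, _ in ivs)
        arr = np.zeros(hi - lo)
        for s, e, v in ivs:
            arr[s - lo : e - lo] = v
        scores[chrom] = arr
        offset[chrom] = lo + 1
    return ConservationTrack(scores, offset)


def region_conservation(
    site: BindingSite, track: ConservationTrack, window: int = 100
) -> float:
    """Maximum ``window``-bp moving average of per-base scores in the site.

    Windows are fully contained in the site; sites shorter than the window
    use the mean over the whole site.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    scores = track.per_base(site.chrom, site.start, site.end)
    n = len(scores)
    if n < window:
        return float(scores.mean())
    cs = np.concatenate([[0.0], np.cumsum(scores)])
    sliding = (cs[window:] - cs[:-window]) / window
    return float(sliding.max())


def select_threshold(bound_scores, background_scores) -> float:
    """Threshold that best separates bound regions from background.

    Maximizes (fraction of bound scores > t) + (fraction of background
    scores <= t) over the midpoints of adjacent sorted unique pooled
    scores; ties break toward the smaller threshold.
    """
    bound = np.asarray(bound_scores, dtype=float)
    background = np.asarray(background_scores, dtype=float)
    if bound.size == 0 or background.size == 0:
        raise ValueError("both score lists must be non-empty")
    pooled = np.unique(np.concatenate([bound, background]))
    if pooled.size == 1:
        return float(pooled[0])
    candidates = (pooled[:-1] + pooled[1:]) / 2.0
    best_t, best_j = None, -np.inf
    for t in candidates:
        j = np.mean(bound > t) + np.mean(background <= t)
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t


def partition_conserved(
    sites: list[BindingSite], threshold: float
) -> tuple[list[BindingSite], list[BindingSite]]:
    """Split sites into (conserved, nonconserved) by score > threshold."""
    conserved, nonconserved = [], []
    for s in sites:
        if s.conservation is None:
            raise ValueError(f"site {s.site_id} has no conservation score")
        (conserved if s.conservation > threshold else nonconserved).append(s)
    return conserved, nonconserved
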