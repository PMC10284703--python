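"""Copy-number inference from B-allele frequencies and coverage ratios.

Germline-heterozygous SNVs carry two signals: the mirrored B-allele frequency
|BAF - 0.5| rises under allelic imbalance, and the log2 coverage ratio versus
the germline falls under deletion. Fixed-window median smoothing of both
tracks, followed by thresholding and run merging, yields segments classified
as one-copy loss (BAF shift + coverage drop), copy-neutral LOH (BAF shift,
no coverage drop) or focal homozygous deletion (coverage collapse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CNASegment:
    chrom: str
    start: int   # 1-based inclusive
    end: int
    call: str    # loss | cnloh | homdel | neutral
    n_snvs: int
    mean_mirrored_baf: float
    mean_log2_ratio: float


@dataclass
class CNAParams:
    window: int = 50            # SNVs per smoothing window
    baf_shift: float = 0.1      # |median BAF - 0.5| above this => imbalance
    ratio_drop: float = 0.3     # |median log2 ratio| above this => coverage change
    homdel_floor: float = 0.25  # coverage ratio (linear) below this => homozygous deletion


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=max(1, window // 2)).median().to_numpy()


def infer_cna(track: pd.DataFrame, params: CNAParams | None = None) -> list[CNASegment]:
    """Segment a BAF/coverage track into copy-number calls.

    ``track`` must carry columns ``chrom, pos, baf, log2_ratio`` sorted by
    position within each chromosome (rows are germline-het SNVs). Returns
    non-neutral segments only; an empty track yields an empty list.
    """
    params = params or CNAParams()
    if track.empty:
        return []
    segments: list[CNASegment] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        mirrored = np.abs(sub["baf"].to_numpy() - 0.5)
        ratio = sub["log2_ratio"].to_numpy()
        sm_baf = _rolling_median(mirrored, params.window)
        sm_ratio = _rolling_median(ratio, params.window)
        lin_ratio = 2.0 ** sm_ratio
        state = np.full(len(sub), "neutral", dtype=object)
        state[(sm_baf > params.baf_shift) & (sm_ratio < -params.ratio_drop)] = "loss"
        state[(sm_baf > params.baf_shift) & (np.abs(sm_ratio) <= params.ratio_drop)] = "cnloh"
        state[lin_ratio < params.homdel_floor] = "homdel"
        pos = sub["pos"].to_numpy()
        i = 0
        while i < len(state):
            j = i
            while j + 1 < len(state) and state[j + 1] == state[i]:
                j += 1
            if state[i] != "neutral":
                segments.append(
                    CNASegment(
                        chrom=str(chrom),
                        start=int(pos[i]),
                        end=int(pos[j]),
                        call=str(state[i]),
                        n_snvs=j - i + 1,
                        mean_mirrored_baf=float(np.nanmean(sm_baf[i : j + 1])),
                        mean_log2_ratio=float(np.nanmean(sm_ratio[i : j + 1])),
                    )
                )
            i = j + 1
    # drop flicker: segments supported by fewer SNVs than half a window
    return [s for s in segments if s.n_snvs >= max(3, (params.window // 2))]


def segments_to_mask(segments: list[CNASegment], variants: pd.DataFrame) -> pd.Index:
    """Variant ids (rows of ``variants`` with chrom/pos) inside any segment."""
    hit = []
    for vid, row in variants.iterrows():
        for s in segments:
            if row["chrom"] == s.chrom and s.start <= row["pos"] <= s.end:
                hit.append(vid)
                break
    return pd.Index(hit)


@dataclass
class PhasedBAF:
    assignments: pd.Series   # per SNV: haplotype 'A' or 'B'
    phased: pd.DataFrame     # per SNV x sample: BAF of the A haplotype
    anchor_sample: str | None
    indeterminate: bool
    low_confidence: bool


def phase_baf(baf_by_sample: pd.DataFrame, min_shift: float = 0.05) -> PhasedBAF:
    """Phase het SNVs within one segment across samples.

    ``baf_by_sample`` is SNVs x samples. The most allele-imbalanced sample
    anchors the phase: SNVs with BAF above 0.5 there are assigned to one
    haplotype, below to the other; the assignment is then applied to every
    sample so that losses of different alleles in different samples appear as
    mirrored tracks. With no sample shifted beyond ``min_shift`` the phasing
    is declared indeterminate; a single-SNV segment is assigned but flagged
    low-confidence.
    """
    shifts = (baf_by_sample - 0.5).abs().mean(axis=0)
    anchor = shifts.idxmax()
    if shifts[anchor] <= min_shift:
        return PhasedBAF(
            assignments=pd.Series("", index=baf_by_sample.index),
            phased=baf_by_sample * np.nan,
            anchor_sample=None,
            indeterminate=True,
            low_confidence=True,
        )
    hap = pd.Series(
        np.where(baf_by_sample[anchor] >= 0.5, "B", "A"), index=baf_by_sample.index
    )
    phased = baf_by_sample.copy()
    flip = hap == "B"
    phased.loc[flip] = 1.0 - baf_by_sample.loc[flip]
    return PhasedBAF(
        assignments=hap,
        phased=phased,
        anchor_sample=anchor,
        indeterminate=False,
        low_confidence=len(baf_by_sample) < 2,
    )
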