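"""Lobar integration: dominance calls, MSS, FO and the flexibility index.

A coupling mode (estimator id, frequency code) is *dominant* for a lobar
sensor block when it is displayed by more than 75% of the block's sensor
pairs within a temporal segment, in at least 50% of all segments.  Over the
dominant segments the mean subgraph strength (MSS) averages the retained
coupling strengths across the block's sensor pairs, and the fractional
occupancy (FO) is the share of segments in which the mode dominates.  The
flexibility index (FI) is the rate of coupling-mode label changes between
consecutive segments, averaged over all sensor pairs; all three quantities
lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import LobarLayout, SubnetworkSpec
from .surrogate_stats import DicmTensor

SENSOR_PAIR_THRESHOLD = 0.75   # strict: fraction must exceed this
SEGMENT_THRESHOLD = 0.5        # inclusive: at least half of all segments


def mode_label(est: int, code: int) -> int:
    """Combined integer label of a coupling mode; 0 = no coupling."""
    return int(est) * 100 + int(code) if code else 0


def block_pair_indices(
    tensor_pairs: list[tuple[int, int]],
    channel_names: list[str],
    layout: LobarLayout,
    lobe_a: str,
    lobe_b: str,
    scope: str,
    hemi_a: str | None = None,
) -> np.ndarray:
    """Indices (into the tensor's pair axis) of one lobar sensor block.

    ``scope``: "cross" = inter-hemispheric pairs, "within" =
    intra-hemispheric pairs, "both" = all pairs between the two lobes.
    ``hemi_a`` restricts the lobe_a side to one hemisphere.
    """
    idx = {
        (lobe, h): set(layout.indices(channel_names, lobe, h))
        for lobe in {lobe_a, lobe_b}
        for h in ("L", "R")
    }
    hemis_a = [hemi_a] if hemi_a else ["L", "R"]
    wanted: set[tuple[int, int]] = set()

    def add(sa: set[int], sb: set[int]) -> None:
        for i in sa:
            for j in sb:
                if i != j:
                    wanted.add((min(i, j), max(i, j)))

    for ha in hemis_a:
        for hb in ("L", "R"):
            same_hemi = ha == hb
            if scope == "cross" and same_hemi:
                continue
            if scope == "within" and not same_hemi:
                continue
            add(idx[(lobe_a, ha)], idx[(lobe_b, hb)])
    if not wanted:
        raise ValueError(
            f"empty sensor block: {lobe_a}-{lobe_b} scope={scope} hemi_a={hemi_a}"
        )
    pair_pos = {pair: k for k, pair in enumerate(tensor_pairs)}
    return np.array(sorted(pair_pos[p] for p in wanted if p in pair_pos), dtype=int)


def _mode_presence(dicm: DicmTensor, block: np.ndarray, label: int) -> np.ndarray:
    """(T, len(block)) bool: does either retained record match the mode?"""
    lab0 = dicm.est[0][:, block] * 100 + dicm.code[0][:, block]
    lab1 = dicm.est[1][:, block] * 100 + dicm.code[1][:, block]
    present0 = (dicm.code[0][:, block] > 0) & (lab0 == label)
    present1 = (dicm.code[1][:, block] > 0) & (lab1 == label)
    return present0 | present1


@dataclass
class DominanceResult:
    """Dominance call for one lobar block and one coupling mode."""

    label: int
    sensor_fraction: np.ndarray   # per segment, fraction of block pairs
    n_dom: int                    # segments with fraction > 0.75
    n_ts: int                     # total segments
    dominant: bool

    @property
    def segment_fraction(self) -> float:
        return self.n_dom / self.n_ts if self.n_ts else 0.0


def dominance(
    dicm: DicmTensor,
    layout: LobarLayout,
    lobe_a: str,
    lobe_b: str,
    scope: str,
    est: int,
    code: int,
    hemi_a: str | None = None,
) -> DominanceResult:
    """Apply the >75%-of-sensor-pairs / >=50%-of-segments dominance rule."""
    block = block_pair_indices(dicm.pairs, dicm.channel_names, layout,
                               lobe_a, lobe_b, scope, hemi_a)
    label = mode_label(est, code)
    presence = _mode_presence(dicm, block, label)
    frac = presence.mean(axis=1)
    dom_seg = frac > SENSOR_PAIR_THRESHOLD
    n_dom = int(dom_seg.sum())
    return DominanceResult(
        label=label,
        sensor_fraction=frac,
        n_dom=n_dom,
        n_ts=dicm.T,
        dominant=n_dom >= SEGMENT_THRESHOLD * dicm.T,
    )


def mss(
    dicm: DicmTensor,
    layout: LobarLayout,
    lobe_a: str,
    lobe_b: str,
    scope: str,
    est: int,
    code: int,
    hemi_a: str | None = None,
) -> float:
    """Mean subgraph strength of a mode over its dominant segments.

    Per dominant segment the retained strengths of pairs displaying the
    mode are summed and normalized by the block's pair count; segments are
    then averaged.  Zero (flagged by the caller via :func:`dominance`) when
    the mode never dominates a segment.
    """
    block = block_pair_indices(dicm.pairs, dicm.channel_names, layout,
                               lobe_a, lobe_b, scope, hemi_a)
    label = mode_label(est, code)
    presence = _mode_presence(dicm, block, label)
    dom_seg = presence.mean(axis=1) > SENSOR_PAIR_THRESHOLD
    if not dom_seg.any():
        return 0.0
    s0 = np.where(
        (dicm.code[0][:, block] > 0)
        & (dicm.est[0][:, block] * 100 + dicm.code[0][:, block] == label),
        np.nan_to_num(dicm.strength[0][:, block]),
        0.0,
    )
    s1 = np.where(
        (dicm.code[1][:, block] > 0)
        & (dicm.est[1][:, block] * 100 + dicm.code[1][:, block] == label),
        np.nan_to_num(dicm.strength[1][:, block]),
        0.0,
    )
    strengths = np.where(s0 > 0, s0, s1)
    per_segment = strengths[dom_seg].sum(axis=1) / len(block)
    return float(per_segment.mean())


def fo(
    dicm: DicmTensor,
    layout: LobarLayout,
    lobe_a: str,
    lobe_b: str,
    scope: str,
    est: int,
    code: int,
    hemi_a: str | None = None,
) -> float:
    """Fractional occupancy: N_Dom / N_TS for a mode and lobar block."""
    res = dominance(dicm, layout, lobe_a, lobe_b, scope, est, code, hemi_a)
    return res.segment_fraction


@dataclass
class FlexibilityResult:
    fi_global: float
    fi_pairs: np.ndarray


def flexibility(dicm: DicmTensor) -> FlexibilityResult:
    """Flexibility index: rate of coupling-mode label changes.

    Per pair, the number of label changes between consecutive segments
    divided by T-1 (transitions to or from "no coupling" count); the global
    index averages over all pairs.  Labels come from the smaller-p record,
    which defines the cell's identity.
    """
    if dicm.T < 2:
        raise ValueError("flexibility needs at least 2 temporal segments")
    labels = dicm.primary_labels()
    changes = labels[1:] != labels[:-1]
    fi_pairs = changes.mean(axis=0)
    return FlexibilityResult(fi_global=float(fi_pairs.mean()), fi_pairs=fi_pairs)


def flexibility_from_labels(labels: np.ndarray) -> FlexibilityResult:
    """Flexibility of a raw (T, n_pairs) label array (labels are opaque)."""
    labels = np.atleast_2d(np.asarray(labels))
    if labels.shape[0] < 2:
        raise ValueError("flexibility needs at least 2 temporal segments")
    changes = labels[1:] != labels[:-1]
    fi_pairs = changes.mean(axis=0)
    return FlexibilityResult(fi_global=float(fi_pairs.mean()), fi_pairs=fi_pairs)


@dataclass
class SubnetworkFeatureVector:
    """12 MSS + 10 FO values keyed by the packaged subnetwork table."""

    mss_values: dict[str, float] = field(default_factory=dict)
    fo_values: dict[str, float] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.mss_values.values())
                        + list(self.fo_values.values()))

    @property
    def names(self) -> list[str]:
        return [f"mss_{k}" for k in self.mss_values] + [
            f"fo_{k}" for k in self.fo_values
        ]


def feature_vector(
    dicm: DicmTensor,
    layout: LobarLayout,
    spec: SubnetworkSpec,
) -> SubnetworkFeatureVector:
    """Evaluate the subnetwork table: one MSS per row, FO where flagged.

    Rows whose mode never dominates a segment contribute 0 and are listed
    in ``missing``.
    """
    out = SubnetworkFeatureVector()
    for row in spec.rows:
        args = (dicm, layout, row.lobe_a, row.lobe_b, row.scope,
                row.estimator, row.code, row.hemi_a)
        dom = dominance(*args)
        out.mss_values[row.name] = mss(*args)
        if row.has_fo:
            out.fo_values[row.name] = dom.segment_fraction
        if dom.n_dom == 0:
            out.missing.add(row.name)
    return out
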