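"""Matrix-level filtering and normalisation from raw counts to analysis input.

The chain mirrors the standard treatment of depth-profile amplicon data:

1. :func:`merge_replicates` - sum replicate cores per sampling position;
2. :func:`filter_low_count_otus` - drop OTUs with fewer than 10 reads in
   total (likely PCR/sequencing errors);
3. :func:`remove_control_otus` - discard every OTU observed in a negative
   control, and the control rows themselves;
4. :func:`rarefy` - subsample each position without replacement to a
   common total (default 1000 reads), dropping shallower positions; this
   branch feeds richness, habitat-preference and distance analyses;
5. :func:`prevalence_filter` - per depth class, keep OTUs present at a
   third or more of positions; this branch (applied to the *unrarefied*
   merged matrix) feeds co-occurrence network inference, since rarefying
   can introduce artifacts into compositional correlation estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .io import CommunityMatrix, SampleMeta

__all__ = [
    "PreprocessReport",
    "merge_replicates",
    "filter_low_count_otus",
    "remove_control_otus",
    "rarefy",
    "prevalence_filter",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Per-step record of what a preprocessing operation removed."""

    step: str
    n_samples_in: int
    n_samples_out: int
    n_otus_in: int
    n_otus_out: int
    dropped_samples: list[str] = field(default_factory=list)
    dropped_otus: list[str] = field(default_factory=list)
    seed: int | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "n_otus_in": self.n_otus_in,
            "n_otus_out": self.n_otus_out,
            "n_dropped_samples": len(self.dropped_samples),
            "n_dropped_otus": len(self.dropped_otus),
            "dropped_samples": self.dropped_samples,
            "dropped_otus": self.dropped_otus,
            "seed": self.seed,
            "notes": self.notes,
        }


def merge_replicates(matrix: CommunityMatrix) -> tuple[CommunityMatrix, PreprocessReport]:
    """Sum replicate rows per (depth_class, horizontal_position_m).

    Negative-control samples are never merged and pass through unchanged.
    Positions represented by a single replicate keep that replicate's
    counts; the anomaly is logged in the report.
    """
    if matrix.samples is None:
        raise ValueError("merge_replicates requires sample metadata")
    report = PreprocessReport(
        step="merge_replicates",
        n_samples_in=matrix.n_samples,
        n_samples_out=0,
        n_otus_in=matrix.n_otus,
        n_otus_out=matrix.n_otus,
    )
    groups: dict[tuple[str, float], list[SampleMeta]] = {}
    controls: list[SampleMeta] = []
    for s in matrix.samples:
        if s.is_negative_control:
            controls.append(s)
        else:
            groups.setdefault((s.depth_class, s.horizontal_position_m), []).append(s)

    expected = max((len(v) for v in groups.values()), default=0)
    rows = []
    metas = []
    for (depth_class, x), members in groups.items():
        if len(members) != expected:
            msg = (
                f"position (depth={depth_class}, x={x}) has {len(members)} "
                f"replicate(s), expected {expected}; summing what exists"
            )
            logger.warning(msg)
            report.notes.append(msg)
        first = members[0]
        merged_id = _position_id(first)
        rows.append(
            (merged_id, matrix.counts.loc[[m.sample_id for m in members]].sum(axis=0))
        )
        metas.append(
            SampleMeta(
                sample_id=merged_id,
                depth_class=depth_class,
                depth_value_cm=first.depth_value_cm,
                horizontal_position_m=x,
                replicate_id=0,
                is_negative_control=False,
            )
        )
    for c in controls:
        rows.append((c.sample_id, matrix.counts.loc[c.sample_id]))
        metas.append(c)

    counts = pd.DataFrame(
        {sid: row for sid, row in rows}, index=matrix.counts.columns
    ).T.astype(np.int64)
    counts.index.name = "sample_id"
    merged = CommunityMatrix(counts, metas)
    report.n_samples_out = merged.n_samples
    return merged, report


def _position_id(meta: SampleMeta) -> str:
    """Merged-position id: replicate-suffix-stripped when recognisable."""
    sid = meta.sample_id
    if meta.replicate_id and sid.endswith(f"_r{meta.replicate_id}"):
        return sid[: -len(f"_r{meta.replicate_id}")]
    return f"{meta.depth_class}_x{meta.horizontal_position_m:g}"


def filter_low_count_otus(
    matrix: CommunityMatrix, min_total: int = 10
) -> tuple[CommunityMatrix, PreprocessReport]:
    """Remove OTUs whose total reads across all samples are below ``min_total``.

    The boundary is inclusive on keeps: a column total of ``min_total``
    reads survives, one read fewer does not.
    """
    totals = matrix.counts.sum(axis=0)
    keep = totals[totals >= min_total].index
    dropped = [o for o in matrix.otu_ids if o not in set(keep)]
    out = matrix.subset(otu_ids=list(keep))
    report = PreprocessReport(
        step="filter_low_count_otus",
        n_samples_in=matrix.n_samples,
        n_samples_out=out.n_samples,
        n_otus_in=matrix.n_otus,
        n_otus_out=out.n_otus,
        dropped_otus=dropped,
    )
    return out, report


def remove_control_otus(matrix: CommunityMatrix) -> tuple[CommunityMatrix, PreprocessReport]:
    """Discard OTUs seen in any negative control, then drop the control rows."""
    if matrix.samples is None:
        raise ValueError("remove_control_otus requires sample metadata")
    control_ids = [s.sample_id for s in matrix.samples if s.is_negative_control]
    report = PreprocessReport(
        step="remove_control_otus",
        n_samples_in=matrix.n_samples,
        n_samples_out=matrix.n_samples,
        n_otus_in=matrix.n_otus,
        n_otus_out=matrix.n_otus,
    )
    if not control_ids:
        msg = "no negative-control samples present; control-OTU removal is a no-op"
        logger.info(msg)
        report.notes.append(msg)
        return matrix, report
    contaminated = matrix.counts.loc[control_ids].sum(axis=0)
    dropped_otus = list(contaminated[contaminated > 0].index)
    keep_samples = [sid for sid in matrix.sample_ids if sid not in set(control_ids)]
    keep_otus = [o for o in matrix.otu_ids if o not in set(dropped_otus)]
    out = matrix.subset(sample_ids=keep_samples, otu_ids=keep_otus)
    report.n_samples_out = out.n_samples
    report.n_otus_out = out.n_otus
    report.dropped_samples = control_ids
    report.dropped_otus = dropped_otus
    return out, report


def rarefy(
    matrix: CommunityMatrix, depth: int = 1000, seed: int = 0
) -> tuple[CommunityMatrix, PreprocessReport]:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped; each retained
    sample is drawn once from the multivariate hypergeometric distribution
    over its counts.  OTUs left with zero reads everywhere are removed.
    Deterministic under a fixed ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = matrix.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped_samples = [s for s in matrix.sample_ids if s not in set(keep)]
    sub = matrix.counts.loc[keep]
    out_rows = np.empty_like(sub.to_numpy())
    for r, (_, row) in enumerate(sub.iterrows()):
        out_rows[r] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    rarefied = pd.DataFrame(out_rows, index=sub.index, columns=sub.columns)
    nonzero = rarefied.columns[rarefied.sum(axis=0) > 0]
    dropped_otus = [o for o in matrix.otu_ids if o not in set(nonzero)]
    rarefied = rarefied[nonzero]
    samples = None
    if matrix.samples is not None:
        keep_set = set(rarefied.index)
        samples = [s for s in matrix.samples if s.sample_id in keep_set]
    out = CommunityMatrix(rarefied, samples)
    report = PreprocessReport(
        step="rarefy",
        n_samples_in=matrix.n_samples,
        n_samples_out=out.n_samples,
        n_otus_in=matrix.n_otus,
        n_otus_out=out.n_otus,
        dropped_samples=dropped_samples,
        dropped_otus=dropped_otus,
        seed=seed,
    )
    return out, report


def prevalence_filter(
    matrix: CommunityMatrix,
    depth_class: str,
    min_fraction: Fraction | float = Fraction(1, 3),
) -> CommunityMatrix:
    """Restrict to one depth class, keeping OTUs present at >= ``min_fraction``
    of that depth's sampling positions.

    The occupancy fraction is compared as an exact rational: with 47
    positions and the default third, an OTU needs presence at 16 or more
    positions (47/3 = 15.67).  Presence means one read or more.
    """
    if matrix.samples is None:
        raise ValueError("prevalence_filter requires sample metadata")
    if not isinstance(min_fraction, Fraction):
        min_fraction = Fraction(min_fraction).limit_denominator(10**6)
    sample_ids = [
        s.sample_id
        for s in matrix.samples
        if s.depth_class == depth_class and not s.is_negative_control
    ]
    if not sample_ids:
        known = sorted({s.depth_class for s in matrix.samples})
        raise ValueError(f"unknown or empty depth class {depth_class!r}; have {known}")
    sub = matrix.subset(sample_ids=sample_ids)
    n = sub.n_samples
    occupancy = (sub.counts > 0).sum(axis=0)
    keep = [o for o in sub.otu_ids if Fraction(int(occupancy[o]), n) >= min_fraction]
    return sub.subset(otu_ids=keep)
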