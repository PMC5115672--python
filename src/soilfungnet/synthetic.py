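"""Synthetic depth-stratified OTU count tables with planted structure.

The generator emulates a soil-profile sampling design: ``n_depths`` depth
classes x ``n_positions_per_depth`` horizontal positions x ``n_replicates``
replicate cores.  Each sampling position carries a latent (basis) abundance
vector drawn from a multivariate lognormal whose log-scale means encode
depth-specific habitat preferences and whose log-scale correlations encode
planted pairwise associations.  Observed read counts are multinomial draws
from the position's basis composition with lognormally distributed
per-replicate sequencing totals, so compositional distortion of naive
correlations is present by construction.  A configurable fraction of
positions receives totals below the rarefaction threshold, exercising the
sample-dropping path of the rarefaction step downstream.

Planted effects and the latent basis abundances are returned as
:class:`GroundTruth` so that recovery of preferences and associations can
be tested against known truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import CommunityMatrix, SampleMeta

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_null_dataset",
    "study_depth_classes",
]

#: the study-shaped depth design: label and signed depth (cm) relative to
#: the O-A horizon boundary, shallowest first
_STUDY_DEPTHS: tuple[tuple[str, float], ...] = (
    ("+2cm", 2.0),
    ("0cm", 0.0),
    ("-3cm", -3.0),
    ("-5cm", -5.0),
    ("-10cm", -10.0),
    ("-15cm", -15.0),
    ("-20cm", -20.0),
    ("-30cm", -30.0),
    ("-50cm", -50.0),
    ("-100cm", -100.0),
)


def study_depth_classes(n_depths: int) -> list[tuple[str, float]]:
    """Depth labels/values for ``n_depths`` classes, shallowest first.

    For 10 classes this is the soil-profile design spanning the O horizon
    (+2 cm), the O-A boundary (0 cm) and 3-100 cm below it; for other
    counts an analogous monotone sequence is generated.
    """
    if n_depths <= len(_STUDY_DEPTHS):
        return list(_STUDY_DEPTHS[:n_depths])
    out = list(_STUDY_DEPTHS)
    deepest = out[-1][1]
    for k in range(n_depths - len(out)):
        v = deepest - 50.0 * (k + 1)
        out.append((f"{v:+.0f}cm".replace("+-", "-"), v))
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic community generator.

    Defaults mirror the emulated study design: 10 depth classes x 50
    horizontal positions (20 cm apart along a 9.8 m profile) x 2
    replicates, ~1200 OTUs, strongly uneven per-replicate sequencing
    totals, and ~40% of positions left below the 1000-read rarefaction
    threshold.
    """

    n_depths: int = 10
    n_positions_per_depth: int = 50
    n_replicates: int = 2
    n_otus: int = 1200
    #: per-OTU baseline log abundance ~ Normal(mean, sd); the sd sets the
    #: steepness of the rank-abundance curve
    base_log_abundance_mean: float = 0.0
    base_log_abundance_sd: float = 3.0
    #: sd of the per-position log-scale fluctuation around the baseline;
    #: planted associations correlate these fluctuations
    sample_log_sd: float = 2.0
    #: (otu_id, depth_class) -> additive effect on log basis abundance
    preference_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    #: (otu_i, otu_j, rho) planted basis correlations, |rho| < 1
    association_pairs: tuple[tuple[str, str, float], ...] = ()
    #: per-replicate total reads ~ LogNormal(log-mean, log-sd)
    seq_depth_log_mean: float = math.log(3000.0)
    seq_depth_log_sd: float = 1.2
    #: fraction of sampling positions whose merged total is forced below
    #: the rarefaction threshold (these positions drop out downstream)
    dropout_fraction: float = 0.4
    rarefaction_threshold: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_depths", "n_positions_per_depth", "n_replicates", "n_otus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.rarefaction_threshold < 1:
            raise ValueError("rarefaction_threshold must be >= 1")
        for i, j, rho in self.association_pairs:
            if i == j:
                raise ValueError(f"self-association on {i!r}")
            if not abs(rho) < 1:
                raise ValueError(f"|rho| must be < 1 for pair ({i}, {j})")
        object.__setattr__(
            self, "association_pairs", tuple(tuple(p) for p in self.association_pairs)
        )

    # -- naming helpers -------------------------------------------------------
    def otu_ids(self) -> list[str]:
        width = len(str(self.n_otus))
        return [f"OTU_{k + 1:0{width}d}" for k in range(self.n_otus)]

    def depth_design(self) -> list[tuple[str, float]]:
        return study_depth_classes(self.n_depths)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load a config from JSON or YAML."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if "preference_effects" in raw:
            pe = raw["preference_effects"]
            if isinstance(pe, dict):  # keys written as "OTU|depth_class"
                raw["preference_effects"] = {
                    tuple(str(k).split("|", 1)): float(v) for k, v in pe.items()
                }
            else:  # list of [otu, depth_class, effect]
                raw["preference_effects"] = {
                    (str(o), str(d)): float(v) for o, d, v in pe
                }
        if "association_pairs" in raw:
            raw["association_pairs"] = tuple(
                (str(a), str(b), float(r)) for a, b, r in raw["association_pairs"]
            )
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted structure retained for recovery tests.

    ``basis`` holds the latent per-position basis abundances (positions x
    OTUs) before multinomial observation; association pairs are stored
    with both orderings collapsed to a canonical (sorted) one.
    """

    preference_effects: dict[tuple[str, str], float]
    association_pairs: list[tuple[str, str, float]]
    basis: pd.DataFrame

    def __post_init__(self) -> None:
        canon = []
        seen = set()
        for i, j, rho in self.association_pairs:
            if i == j:
                raise ValueError("self-association in ground truth")
            key = tuple(sorted((i, j)))
            if key in seen:
                raise ValueError(f"duplicate association pair {key}")
            seen.add(key)
            canon.append((key[0], key[1], float(rho)))
        self.association_pairs = canon


def _correlation_matrix(config: SyntheticConfig) -> np.ndarray:
    """Build and validate the planted log-scale correlation matrix."""
    ids = config.otu_ids()
    index = {o: k for k, o in enumerate(ids)}
    corr = np.eye(config.n_otus)
    for i, j, rho in config.association_pairs:
        if i not in index or j not in index:
            raise ValueError(f"association pair ({i}, {j}) references unknown OTU")
        a, b = index[i], index[j]
        corr[a, b] = corr[b, a] = rho
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            "implied basis correlation structure is not positive definite; "
            f"offending pairs: {[(i, j) for i, j, _ in config.association_pairs]}"
        ) from None
    return corr


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[CommunityMatrix, list[SampleMeta], GroundTruth]:
    """Generate a synthetic replicate-level count matrix with known truth.

    Returns the pre-merge matrix (one row per depth x position x
    replicate), the matching metadata, and the :class:`GroundTruth`.
    Output is bit-identical under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    otus = config.otu_ids()
    depths = config.depth_design()
    n_pos = config.n_positions_per_depth
    n_positions = config.n_depths * n_pos
    J = config.n_otus

    corr = _correlation_matrix(config)
    chol = np.linalg.cholesky(corr)

    base = rng.normal(config.base_log_abundance_mean, config.base_log_abundance_sd, size=J)

    # depth-specific log-mean offsets
    effect = np.zeros((config.n_depths, J))
    depth_index = {label: d for d, (label, _) in enumerate(depths)}
    otu_index = {o: k for k, o in enumerate(otus)}
    for (otu, depth_class), eff in config.preference_effects.items():
        if otu not in otu_index:
            raise ValueError(f"preference effect references unknown OTU {otu!r}")
        if depth_class not in depth_index:
            raise ValueError(f"preference effect references unknown depth {depth_class!r}")
        effect[depth_index[depth_class], otu_index[otu]] = eff

    # latent basis abundances per position (replicates share the basis)
    z = rng.standard_normal((n_positions, J))
    depth_of_position = np.repeat(np.arange(config.n_depths), n_pos)
    log_basis = base[None, :] + effect[depth_of_position] + config.sample_log_sd * (z @ chol.T)
    basis = np.exp(log_basis)
    composition = basis / basis.sum(axis=1, keepdims=True)

    # per-replicate sequencing totals; a chosen fraction of positions is
    # forced below the rarefaction threshold (merged across replicates)
    totals = np.maximum(
        1,
        np.round(
            rng.lognormal(config.seq_depth_log_mean, config.seq_depth_log_sd,
                          size=(n_positions, config.n_replicates))
        ).astype(np.int64),
    )
    n_drop = int(round(config.dropout_fraction * n_positions))
    if n_drop:
        drop_positions = rng.choice(n_positions, size=n_drop, replace=False)
        thr = config.rarefaction_threshold
        low = max(1, thr // 10)
        for p in drop_positions:
            merged_target = int(rng.integers(low, thr))
            share = rng.multinomial(merged_target, np.full(config.n_replicates, 1.0 / config.n_replicates))
            totals[p] = np.maximum(1, share)

    position_ids = []
    rows = []
    metas = []
    for p in range(n_positions):
        d = depth_of_position[p]
        label, depth_cm = depths[d]
        x = (p % n_pos) * 0.2  # 20-cm horizontal spacing
        pid = f"d{d + 1:02d}_x{p % n_pos + 1:02d}"
        position_ids.append(pid)
        for r in range(config.n_replicates):
            sid = f"{pid}_r{r + 1}"
            rows.append(rng.multinomial(totals[p, r], composition[p]))
            metas.append(
                SampleMeta(
                    sample_id=sid,
                    depth_class=label,
                    depth_value_cm=depth_cm,
                    horizontal_position_m=round(x, 3),
                    replicate_id=r + 1,
                    is_negative_control=False,
                )
            )

    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=[m.sample_id for m in metas], columns=otus
    )
    truth = GroundTruth(
        preference_effects=dict(config.preference_effects),
        association_pairs=[tuple(p) for p in config.association_pairs],
        basis=pd.DataFrame(basis, index=position_ids, columns=otus),
    )
    return CommunityMatrix(counts, metas), metas, truth


def generate_null_dataset(
    config: SyntheticConfig,
) -> tuple[CommunityMatrix, list[SampleMeta], GroundTruth]:
    """As :func:`generate_dataset` with all planted effects forced to zero.

    Samples are then exchangeable across depth labels: any apparent habitat
    preference or association downstream is a false positive.
    """
    null_config = replace(config, preference_effects={}, association_pairs=())
    return generate_dataset(null_config)
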