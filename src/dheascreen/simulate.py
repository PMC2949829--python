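"""Synthetic two-channel array experiments with planted treatment effects.

Emulates the study design the downstream pipeline expects: 13 animals
(3 IM, 3 PO, 3 CTR1, 4 CTR3), a pooled Cy3 common reference identical in
expectation across arrays, a control-group batch effect (CTR3 shifted versus
CTR1 on a gene subset), and treatment signatures that may be route-specific
or shared between routes. Every random draw flows through one seeded
generator, so identical configs produce bit-identical tables.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import GROUPS, SpotTable

log = logging.getLogger(__name__)

DEFAULT_GROUP_SIZES: Mapping[str, int] = {"IM": 3, "PO": 3, "CTR1": 3, "CTR3": 4}

# Table-1-flavoured metadata defaults per group: (age months, weight kg)
_GROUP_AGE_WEIGHT = {
    "IM": (10, 300),
    "PO": (10, 290),
    "CTR1": (6, 166),
    "CTR3": (13, 384),
}

#: Dynamic range of gene baselines, in log2 units above the background mean.
_BASELINE_LO_OFFSET = 0.8
_BASELINE_SPAN = 7.0

#: Planted genes are drawn from baselines at least this far above the low end,
#: so a planted signature is not erased by the intensity floor by construction.
_AFFECTED_MIN_OFFSET = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment."""

    n_genes: int = 2000
    spots_per_gene: int = 2
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_affected_im: int = 50
    n_affected_po: int = 50
    n_affected_shared: int = 0
    effect_log2: float = 1.0
    batch_shift_log2: float = 0.8
    batch_fraction: float = 0.3
    noise_sd_log2: float = 0.25
    tech_sd_log2: float = 0.1
    background_mean: float = 60.0
    floor_reference: float = 130.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.spots_per_gene < 1:
            raise ConfigurationError("spots_per_gene must be >= 1")
        for f in ("n_affected_im", "n_affected_po", "n_affected_shared"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0")
        n_affected = (self.n_affected_im + self.n_affected_po
                      + self.n_affected_shared)
        if n_affected > self.n_genes:
            raise ConfigurationError(
                "n_affected_im + n_affected_po + n_affected_shared "
                "exceeds n_genes")
        if self.noise_sd_log2 <= 0:
            raise ConfigurationError("noise_sd_log2 must be > 0")
        if self.tech_sd_log2 < 0:
            raise ConfigurationError("tech_sd_log2 must be >= 0")
        if not 0.0 <= self.batch_fraction <= 1.0:
            raise ConfigurationError("batch_fraction must be in [0, 1]")
        if self.background_mean <= 0:
            raise ConfigurationError("background_mean must be > 0")
        if self.floor_reference <= 0:
            raise ConfigurationError("floor_reference must be > 0")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ConfigurationError(
                f"group_sizes has unknown groups {sorted(unknown)}")
        for g in GROUPS:
            if self.group_sizes.get(g, 0) < 0:
                raise ConfigurationError(f"group_sizes[{g}] must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted-effect bookkeeping enabling recovery tests."""

    affected_im: frozenset[str]
    affected_po: frozenset[str]
    affected_shared: frozenset[str]
    batch_genes: frozenset[str]
    effects_log2: dict[str, float]

    def __post_init__(self) -> None:
        sets = [self.affected_im, self.affected_po, self.affected_shared]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                if sets[a] & sets[b]:
                    raise ValueError("affected sets must be pairwise disjoint")

    @property
    def all_affected(self) -> frozenset[str]:
        return self.affected_im | self.affected_po | self.affected_shared

    def to_json(self) -> str:
        return json.dumps(
            {
                "affected_im": sorted(self.affected_im),
                "affected_po": sorted(self.affected_po),
                "affected_shared": sorted(self.affected_shared),
                "batch_genes": sorted(self.batch_genes),
                "effects_log2": dict(sorted(self.effects_log2.items())),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            affected_im=frozenset(d["affected_im"]),
            affected_po=frozenset(d["affected_po"]),
            affected_shared=frozenset(d["affected_shared"]),
            batch_genes=frozenset(d["batch_genes"]),
            effects_log2={k: float(v) for k, v in d["effects_log2"].items()},
        )


def _make_sample_sheet(config: SimConfig, batch_state: dict[str, float]) -> pd.DataFrame:
    """Animal metadata. Treated animals cycle through batches 1..3 as in the
    original three-experiment design; controls sit in their home batch."""
    rows = []
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        age, weight = _GROUP_AGE_WEIGHT[group]
        for k in range(n):
            animal = f"{group}{k + 1}"
            if group == "CTR1":
                batch = 1
            elif group == "CTR3":
                batch = 3
            else:
                batch = (k % 3) + 1
            rows.append({
                "animal_id": animal,
                "group": group,
                "batch": batch,
                "age_months": age,
                "weight_kg": weight,
                "batch_state": batch_state[animal],
            })
    return pd.DataFrame(rows)


def _assign_batch_states(config: SimConfig, rng: np.random.Generator) -> dict[str, float]:
    """Batch-effect multiplier per animal: CTR1 0, CTR3 1; treated animals
    follow their experiment of origin, batch-2 animals drawn from a mixture
    of the two states."""
    states: dict[str, float] = {}
    for group in GROUPS:
        for k in range(config.group_sizes.get(group, 0)):
            animal = f"{group}{k + 1}"
            if group == "CTR1":
                states[animal] = 0.0
            elif group == "CTR3":
                states[animal] = 1.0
            else:
                batch = (k % 3) + 1
                if batch == 1:
                    states[animal] = 0.0
                elif batch == 3:
                    states[animal] = 1.0
                else:
                    states[animal] = float(rng.integers(0, 2))
    return states


def generate_experiment(
    config: SimConfig,
) -> tuple[list[SpotTable], pd.DataFrame, SyntheticTruth]:
    """Generate one full synthetic experiment.

    Returns one :class:`SpotTable` per animal, the sample sheet, and the
    ground truth. The Cy3 channel simulates the pooled common reference (same
    expectation on every array); Cy5 carries baseline + batch + treatment +
    biological noise. Channel values model background-corrected foreground
    signals, with the ``bg`` columns carrying per-spot background estimates,
    so the downstream 2x-background filter excludes the dimmest few percent
    of spots.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    genes = np.array([f"G{i:05d}" for i in range(n)])
    lo = math.log2(config.background_mean) + _BASELINE_LO_OFFSET
    baseline = rng.uniform(lo, lo + _BASELINE_SPAN, size=n)

    # planted genes: disjoint draws among well-expressed genes
    eligible = np.flatnonzero(baseline >= lo + _AFFECTED_MIN_OFFSET)
    n_planted = (config.n_affected_im + config.n_affected_po
                 + config.n_affected_shared)
    if n_planted > len(eligible):
        raise ConfigurationError(
            "n_genes too small for the requested number of affected genes")
    picked = rng.choice(eligible, size=n_planted, replace=False)
    im_idx = picked[: config.n_affected_im]
    po_idx = picked[config.n_affected_im:
                    config.n_affected_im + config.n_affected_po]
    sh_idx = picked[config.n_affected_im + config.n_affected_po:]

    batch_idx = rng.choice(
        n, size=int(round(config.batch_fraction * n)), replace=False)
    batch_mask = np.zeros(n, dtype=bool)
    batch_mask[batch_idx] = True

    effect = np.zeros(n)
    effect[im_idx] = config.effect_log2
    effect[po_idx] = config.effect_log2
    effect[sh_idx] = config.effect_log2
    im_mask = np.zeros(n, dtype=bool)
    im_mask[im_idx] = True
    im_mask[sh_idx] = True
    po_mask = np.zeros(n, dtype=bool)
    po_mask[po_idx] = True
    po_mask[sh_idx] = True

    batch_states = _assign_batch_states(config, rng)
    samples = _make_sample_sheet(config, batch_states)

    s = config.spots_per_gene
    probe_ids = np.array(
        [f"{g}_s{r}" for g in genes for r in range(1, s + 1)])
    gene_col = np.repeat(genes, s)
    base_spot = np.repeat(baseline, s)

    # pooled reference: control-pool average expression per gene
    n_ctr1 = config.group_sizes.get("CTR1", 0)
    n_ctr3 = config.group_sizes.get("CTR3", 0)
    pool_frac = n_ctr3 / max(n_ctr1 + n_ctr3, 1)
    ref_gene = baseline + config.batch_shift_log2 * pool_frac * batch_mask
    ref_spot = np.repeat(ref_gene, s)

    bg_shape = 16.0
    bg_scale = config.background_mean / bg_shape

    tables: list[SpotTable] = []
    for row in samples.itertuples():
        group = row.group
        mu = baseline.copy()
        if group in ("CTR3", "IM", "PO"):
            mu = mu + config.batch_shift_log2 * row.batch_state * batch_mask
        if group == "IM":
            mu = mu + effect * im_mask
        elif group == "PO":
            mu = mu + effect * po_mask
        bio = rng.normal(0.0, config.noise_sd_log2, size=n)
        mu_spot = np.repeat(mu + bio, s)

        tech5 = rng.normal(0.0, config.tech_sd_log2, size=len(mu_spot))
        tech3 = rng.normal(0.0, config.tech_sd_log2, size=len(mu_spot))
        sig5 = np.exp2(mu_spot + tech5)
        sig3 = np.exp2(ref_spot + tech3)
        bg5 = rng.gamma(bg_shape, bg_scale, size=len(mu_spot))
        bg3 = rng.gamma(bg_shape, bg_scale, size=len(mu_spot))

        data = pd.DataFrame({
            "probe_id": probe_ids,
            "gene_id": gene_col,
            "cy5": np.round(sig5, 4),
            "cy3": np.round(sig3, 4),
            "bg5": np.round(bg5, 4),
            "bg3": np.round(bg3, 4),
        })
        tables.append(SpotTable(sample_id=row.animal_id, data=data))

    truth = SyntheticTruth(
        affected_im=frozenset(genes[im_idx]),
        affected_po=frozenset(genes[po_idx]),
        affected_shared=frozenset(genes[sh_idx]),
        batch_genes=frozenset(genes[batch_mask]),
        effects_log2={str(genes[i]): float(effect[i]) for i in picked},
    )
    log.info("simulated %d arrays, %d genes x %d spots; %d planted genes",
             len(tables), n, s, n_planted)
    return tables, samples.drop(columns=["batch_state"]), truth


def generate_null_experiment(
    config: SimConfig,
) -> tuple[list[SpotTable], pd.DataFrame, SyntheticTruth]:
    """As :func:`generate_experiment` with every planted effect forced to
    zero and the truth sets recorded as empty (batch genes are kept)."""
    config.validate()
    tables, samples, truth = generate_experiment(
        replace(config, effect_log2=0.0))
    null_truth = SyntheticTruth(
        affected_im=frozenset(),
        affected_po=frozenset(),
        affected_shared=frozenset(),
        batch_genes=truth.batch_genes,
        effects_log2={},
    )
    return tables, samples, null_truth
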