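"""Generators for qPCR and fatty-acid datasets with known ground truth.

The qPCR generator is the joint mixed model read generatively: per-well
y = TG_gc + P_gj + B_gk + A_gl + D_il + e, with all random components drawn
zero-mean normal on the log2 scale, then inverted to Cp = y / log2(E_g).
The design mirrors the emulated feeding trial: 30 Iberian and 19 Duroc
animals split HO/CH (17/13 and 10/9), both feeding statuses biopsied per
animal, 13 target plus 2 reference genes with the trial's amplification
efficiencies, triplicate wells, gene-balanced plates of ~4 animals, boxes
nested in breed x diet, and 19 litters allocated round-robin within breed.

Treatment effects are injected per gene as named effect sizes d on the
-log2 expression scale (an effect of -log2(f) back-transforms to fold change
f in favour of the first-named class); cell means are
TG_gc = baseline_g + sum_e (d_e / 2) s_ec with s the +-1 sign pattern of the
2x2x2 design, so each named contrast recovers exactly its injected d.

The fatty-acid generator perturbs per-cell mean composition vectors on the
log scale with litter, box and residual noise and closes each sample to
100 %.  Mean vectors are padded with an ``other`` component (unreported
minor fatty acids) up to 100, so a noiseless sample reproduces its mean
vector exactly while the closure invariant still holds.

The two generators consume independently spawned random streams from the
config seed, so changing one simulator's seed never alters the other's
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import study
from .data_model import BREEDS, DIETS, STATUSES, CP_COLUMNS, treatment_design

__all__ = [
    "QpcrSimConfig",
    "FaSimConfig",
    "SimulatedQpcr",
    "simulate_qpcr",
    "simulate_fa",
    "default_fa_cell_means",
]

#: Realistic log2-scale variance components for a well-run qPCR study:
#: plate and animal/sample SDs around 0.2 log2 units, smaller box effects,
#: and ~0.14-cycle-equivalent well noise.
DEFAULT_VARIANCE_COMPONENTS = {
    "plate": 0.02,
    "box": 0.005,
    "animal": 0.04,
    "sample": 0.04,
    "residual": 0.02,
}


def _largest_remainder(total: int, weights: list[int]) -> list[int]:
    """Apportion ``total`` units proportionally to integer weights."""
    if total < len(weights):
        raise ValueError(f"cannot apportion {total} units across {len(weights)} groups "
                         "with at least one each")
    exact = np.array(weights, float) * total / sum(weights)
    base = np.maximum(np.floor(exact).astype(int), 1)
    while base.sum() > total:
        i = int(np.argmax(base))
        base[i] -= 1
    rem = exact - base
    for _ in range(total - base.sum()):
        i = int(np.argmax(rem))
        base[i] += 1
        rem[i] = -1
    return base.tolist()


@dataclass
class QpcrSimConfig:
    """Study design, truth and noise levels for the qPCR generator."""

    n_iberian: int = 30
    n_duroc: int = 19
    diet_counts: dict = field(default_factory=lambda: dict(study.CELL_COUNTS))
    target_genes: tuple[str, ...] = study.TARGET_GENES
    reference_genes: tuple[str, ...] = study.REFERENCE_GENES
    efficiency_percent: dict[str, float] = field(
        default_factory=lambda: dict(study.EFFICIENCY_PERCENT))
    baseline_y: float | dict[str, float] = 22.0
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    variance_components: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_COMPONENTS))
    replicates: int = 3
    animals_per_plate: int = 4
    n_boxes: int = 10
    n_litters: int = study.N_LITTERS
    seed: int = 0

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.target_genes) + tuple(self.reference_genes)

    def validate(self) -> None:
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be non-negative")
        for g in self.genes:
            if g not in self.efficiency_percent:
                raise ValueError(f"no efficiency for gene {g!r}")
            if not (0 < self.efficiency_percent[g] <= 100):
                raise ValueError(f"efficiency for {g!r} must lie in (0, 100] percent")


@dataclass
class SimulatedQpcr:
    """A simulated well table with its generating truth."""

    wells: pd.DataFrame
    efficiencies: dict[str, float]
    cell_means: pd.DataFrame          # genes x 8 treatment cells, y scale
    config: QpcrSimConfig

    def truth_dict(self) -> dict:
        return {
            "effects": self.config.effects,
            "variance_components": dict(self.config.variance_components),
            "cell_means": {g: {"|".join(c): float(v) for c, v in row.items()}
                           for g, row in self.cell_means.iterrows()},
        }


def _animal_frame(cfg: QpcrSimConfig) -> pd.DataFrame:
    """Animals with breed, diet, litter, box and plate assignments."""
    rows = []
    litter_split = _largest_remainder(
        cfg.n_litters, [cfg.n_iberian, cfg.n_duroc])
    litter_pools = {
        "Iberian": [f"L{i + 1:02d}" for i in range(litter_split[0])],
        "Duroc": [f"L{i + 1 + litter_split[0]:02d}" for i in range(litter_split[1])],
    }
    cells = [(b, d) for b in BREEDS for d in DIETS]
    counts = [cfg.diet_counts[c] for c in cells]
    box_split = _largest_remainder(cfg.n_boxes, counts)
    box_id = 0
    counters = {b: 0 for b in BREEDS}
    aid = {"Iberian": 0, "Duroc": 0}
    for (breed, diet), n_animals, n_cell_boxes in zip(cells, counts, box_split):
        boxes = [f"B{box_id + i + 1:02d}" for i in range(n_cell_boxes)]
        box_id += n_cell_boxes
        for i in range(n_animals):
            aid[breed] += 1
            name = f"{'IB' if breed == 'Iberian' else 'DU'}{aid[breed]:02d}"
            litters = litter_pools[breed]
            rows.append(dict(animal=name, breed=breed, diet=diet,
                             litter=litters[counters[breed] % len(litters)],
                             box=boxes[i % n_cell_boxes]))
            counters[breed] += 1
    df = pd.DataFrame(rows)
    # round-robin keeps plates crossed with breed and diet (balanced plates),
    # so plate effects cancel in treatment contrasts and stay identifiable
    n_plates = max(1, -(-len(df) // cfg.animals_per_plate))
    df["plate"] = [f"P{i % n_plates + 1:02d}" for i in range(len(df))]
    return df


def _cell_means(cfg: QpcrSimConfig) -> pd.DataFrame:
    design = treatment_design()
    genes = cfg.genes
    base = cfg.baseline_y
    sign = {}
    for name in ("breed", "diet", "status"):
        idx = {"breed": 0, "diet": 1, "status": 2}[name]
        first = (BREEDS, DIETS, STATUSES)[idx][0]
        sign[name] = np.array([1.0 if c[idx] == first else -1.0 for c in design.cells])
    for a, b in (("breed", "status"), ("breed", "diet"), ("diet", "status")):
        sign[f"{a}x{b}"] = sign[a] * sign[b]
    rows = {}
    for g in genes:
        mu = np.full(8, float(base[g] if isinstance(base, dict) else base))
        for effect, d in cfg.effects.get(g, {}).items():
            mu += 0.5 * d * sign[effect]
        rows[g] = dict(zip(design.cells, mu))
    return pd.DataFrame.from_dict(rows, orient="index")


def simulate_qpcr(cfg: QpcrSimConfig | None = None) -> SimulatedQpcr:
    """Draw one well table from the generative mixed model.

    Identical configs (including seed) give bit-identical tables.
    """
    cfg = cfg or QpcrSimConfig()
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))
    animals = _animal_frame(cfg)
    genes = cfg.genes
    eff = {g: 1.0 + cfg.efficiency_percent[g] / 100.0 for g in genes}
    means = _cell_means(cfg)
    vc = cfg.variance_components
    design = treatment_design()

    mean_lookup = {g: {cell: float(means.loc[g].iloc[i])
                       for i, cell in enumerate(means.columns)} for g in genes}
    plates = animals["plate"].unique()
    boxes = animals["box"].unique()
    sd = {k: float(np.sqrt(vc[k])) for k in vc}
    P = {(g, j): rng.normal(0, sd["plate"]) for g in genes for j in plates}
    B = {(g, k): rng.normal(0, sd["box"]) for g in genes for k in boxes}
    A = {(g, a): rng.normal(0, sd["animal"]) for g in genes for a in animals["animal"]}
    D = {(a, s): rng.normal(0, sd["sample"]) for a in animals["animal"] for s in STATUSES}

    rows = []
    for _, an in animals.iterrows():
        for status in STATUSES:
            cell = (an["breed"], an["diet"], status)
            for g in genes:
                mu = mean_lookup[g][cell]
                base = (mu + P[(g, an["plate"])] + B[(g, an["box"])]
                        + A[(g, an["animal"])] + D[(an["animal"], status)])
                for r in range(1, cfg.replicates + 1):
                    y = base + rng.normal(0, sd["residual"])
                    rows.append((g, an["animal"], an["breed"], an["diet"], status,
                                 an["plate"], an["box"], r, y / np.log2(eff[g])))
    wells = pd.DataFrame(rows, columns=CP_COLUMNS)
    assert design.cells == tuple(means.columns)
    return SimulatedQpcr(wells=wells, efficiencies=eff, cell_means=means, config=cfg)


# ---------------------------------------------------------------------------
# fatty-acid composition generator
# ---------------------------------------------------------------------------

def default_fa_cell_means(depot: str = "backfat") -> dict[tuple[str, str], dict[str, float]]:
    """Breed x diet cell mean FA vectors built additively from the reference
    margins (cell = breed + diet - grand mean, clipped at 0)."""
    table = study.backfat_lsmeans() if depot == "backfat" else study.ham_lsmeans()
    grand = (table["Duroc"] + table["Iberian"]) / 2.0
    out = {}
    for breed in BREEDS:
        for diet in DIETS:
            vec = (table[breed] + table[diet] - grand).clip(lower=0.0)
            out[(breed, diet)] = vec.to_dict()
    return out


def closed_mean_vector(vec: dict[str, float], fa_names: list[str]) -> np.ndarray:
    """Complete a mean composition to exactly 100 %.

    Vectors summing below 100 are padded through the ``other`` component
    (unreported minor fatty acids), so the named entries are preserved
    exactly; vectors already above 100 (possible for printed LS-mean margins)
    are closed multiplicatively instead.
    """
    mean = np.array([vec.get(f, 0.0) for f in fa_names], float)
    total = mean.sum()
    if "other" not in vec and "other" in fa_names:
        if total <= 100.0:
            mean[fa_names.index("other")] = 100.0 - total
        else:
            mean *= 100.0 / total
    return mean


@dataclass
class FaSimConfig:
    """Cell mean compositions and noise levels for the FA generator.

    Noise SDs are on the log scale; litter and box draws are vectors over
    fatty acids, shared by all samples of the level.
    """

    mean_vectors: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=default_fa_cell_means)
    samples_per_cell: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(study.CELL_COUNTS))
    depot: str = "backfat"
    layer: str = "inner"
    litter_sd: float = 0.05
    box_sd: float = 0.03
    residual_sd: float = 0.08
    n_litters: int = study.N_LITTERS
    n_boxes: int = 10
    seed: int = 0

    def validate(self) -> None:
        for cell, vec in self.mean_vectors.items():
            if any(v < 0 for v in vec.values()):
                raise ValueError(f"negative mean percentage in cell {cell}")
        if min(self.litter_sd, self.box_sd, self.residual_sd) < 0:
            raise ValueError("noise SDs must be non-negative")


def simulate_fa(cfg: FaSimConfig | None = None) -> pd.DataFrame:
    """Draw one fatty-acid profile table; same seed gives identical output.

    Each sample perturbs its cell's mean vector (padded with ``other`` to
    100) on the log scale and is closed back to 100 %; zero mean entries stay
    exactly zero.
    """
    cfg = cfg or FaSimConfig()
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2,)))
    cells = list(cfg.mean_vectors)
    fa_names = list(next(iter(cfg.mean_vectors.values())))
    if "other" not in fa_names:
        fa_names = fa_names + ["other"]

    breeds = sorted({b for b, _ in cells})
    litter_split = _largest_remainder(cfg.n_litters, [
        sum(cfg.samples_per_cell[c] for c in cells if c[0] == b) for b in breeds])
    litter_pools, start = {}, 0
    for b, k in zip(breeds, litter_split):
        litter_pools[b] = [f"L{start + i + 1:02d}" for i in range(k)]
        start += k
    box_split = _largest_remainder(cfg.n_boxes, [cfg.samples_per_cell[c] for c in cells])

    n_fa = len(fa_names)
    litter_eff = {}
    box_eff = {}
    rows = []
    sample_id = 0
    box_id = 0
    litter_counter = {b: 0 for b in breeds}
    for cell, n_cell_boxes in zip(cells, box_split):
        breed, diet = cell
        mean = closed_mean_vector(cfg.mean_vectors[cell], fa_names)
        boxes = [f"B{box_id + i + 1:02d}" for i in range(n_cell_boxes)]
        box_id += n_cell_boxes
        pos = mean > 0
        for i in range(cfg.samples_per_cell[cell]):
            sample_id += 1
            litters = litter_pools[breed]
            litter = litters[litter_counter[breed] % len(litters)]
            litter_counter[breed] += 1
            box = boxes[i % n_cell_boxes]
            if litter not in litter_eff:
                litter_eff[litter] = rng.normal(0, cfg.litter_sd, n_fa)
            if box not in box_eff:
                box_eff[box] = rng.normal(0, cfg.box_sd, n_fa)
            z = np.zeros(n_fa)
            z[pos] = (np.log(mean[pos]) + litter_eff[litter][pos] + box_eff[box][pos]
                      + rng.normal(0, cfg.residual_sd, int(pos.sum())))
            x = np.where(pos, np.exp(z), 0.0)
            x = x * (100.0 / x.sum())
            row = dict(sample=f"S{sample_id:03d}", depot=cfg.depot, layer=cfg.layer,
                       breed=breed, diet=diet, litter=litter, box=box)
            row.update(dict(zip(fa_names, x)))
            rows.append(row)
    return pd.DataFrame(rows)
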