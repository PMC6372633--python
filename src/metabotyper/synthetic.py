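"""Synthetic study generator with recorded ground truth.

Emulates a factorial design (genotypes x tissues x water regimes x
replicates) producing per-plant biomass obeying a power-law shoot-root
relationship, a log-normal metabolite feature table with planted tissue /
genotype / drought / biomass effects, blank samples carrying background
features, and injected zeros and extreme outliers whose coordinates are
recorded so downstream filters can be scored against truth.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .seeds import substream
from .tables import BiomassTable, FeatureTable

TISSUES = ("aboveground", "belowground")
REGIMES = ("control", "drought")


@dataclass(frozen=True)
class DesignSpec:
    """Shape of the simulated study."""

    n_genotypes: int = 30
    n_replicates: int = 5
    tissues: tuple = TISSUES
    regimes: tuple = REGIMES
    n_features: int = 2897
    seed: int = 0

    def validate(self) -> None:
        if self.n_genotypes < 2:
            raise ConfigError("n_genotypes must be >= 2")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.n_features < 40:
            raise ConfigError("n_features must be >= 40 to hold all planted feature groups")
        if len(self.tissues) != 2 or len(self.regimes) != 2:
            raise ConfigError("exactly two tissues and two regimes are supported")

    @property
    def genotypes(self) -> list[str]:
        width = len(str(self.n_genotypes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]


@dataclass(frozen=True)
class EffectSizes:
    """Log-scale additive effect magnitudes for planted feature groups.

    Defaults are ordered so the tissue contrast dominates total variance,
    the genotype signatures are clearly clusterable, and the regime shift
    is the weakest main effect.
    """

    tissue: float = 3.0
    genotype: float = 2.5
    regime: float = 0.4
    biomass: float = 0.8
    noise_sd: float = 0.5
    baseline_mean: float = 9.0
    baseline_sd: float = 1.0

    def validate(self) -> None:
        if self.tissue < self.genotype or self.tissue < self.regime:
            raise ConfigError(
                "effect sizes must satisfy tissue >= genotype and tissue >= regime"
            )
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Planted parameters and coordinates for scoring downstream stages."""

    n_features: int
    ln_b: dict[str, float]
    k: dict[str, float]
    drought_shoot_mult: dict[str, float]
    drought_root_mult: dict[str, float]
    background_features: list[str]
    tissue_marker_features: list[str]
    genotype_marker_features: dict[str, list[str]]
    drought_features: list[str]
    biomass_features: list[str]
    outlier_cells: list[tuple[str, str]] = field(default_factory=list)
    zero_cells: list[tuple[str, str]] = field(default_factory=list)

    def all_genotype_markers(self) -> list[str]:
        out: list[str] = []
        for feats in self.genotype_marker_features.values():
            out.extend(feats)
        return out

    def validate_disjoint(self) -> None:
        groups = [
            set(self.background_features),
            set(self.tissue_marker_features),
            set(self.all_genotype_markers()),
            set(self.drought_features),
            set(self.biomass_features),
        ]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] & groups[j]:
                    raise ConfigError("planted feature groups must be disjoint")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["outlier_cells"] = [list(t) for t in self.outlier_cells]
        d["zero_cells"] = [list(t) for t in self.zero_cells]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["outlier_cells"] = [tuple(t) for t in d["outlier_cells"]]
        d["zero_cells"] = [tuple(t) for t in d["zero_cells"]]
        return cls(**d)


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """One metadata record per plant per tissue.

    Every genotype x regime cell holds exactly ``n_replicates`` plants;
    plant and sample identifiers are unique and deterministic.
    """
    spec.validate()
    records = []
    for geno in spec.genotypes:
        for regime in spec.regimes:
            for rep in range(1, spec.n_replicates + 1):
                plant_id = f"{geno}_{regime}_r{rep}"
                for tissue in spec.tissues:
                    records.append(
                        {
                            "sample_id": f"{plant_id}_{tissue}",
                            "plant_id": plant_id,
                            "genotype": geno,
                            "tissue": tissue,
                            "regime": regime,
                            "replicate": rep,
                        }
                    )
    meta = pd.DataFrame.from_records(records).set_index("sample_id")
    return meta


def _allocate_features(spec: DesignSpec) -> dict:
    """Deterministically partition the feature axis into planted groups."""
    F = spec.n_features
    n_bg = max(4, F // 60)
    n_tissue = max(8, int(0.30 * F))
    n_drought = max(4, int(0.04 * F))
    n_geno_per = max(2, int(0.01 * F))
    n_geno = n_geno_per * spec.n_genotypes
    n_biomass = max(4, min(20, F // 100))
    need = n_bg + n_tissue + n_drought + n_geno + n_biomass
    if need > F:
        raise ConfigError(
            f"n_features={F} too small for planted groups (need >= {need})"
        )
    width = len(str(F))
    names = [f"F{i + 1:0{width}d}" for i in range(F)]
    cursor = 0

    def take(n):
        nonlocal cursor
        out = names[cursor : cursor + n]
        cursor += n
        return out

    background = take(n_bg)
    tissue_markers = take(n_tissue)
    drought_feats = take(n_drought)
    geno_markers = {g: take(n_geno_per) for g in spec.genotypes}
    biomass_feats = take(n_biomass)
    return {
        "names": names,
        "background": background,
        "tissue": tissue_markers,
        "drought": drought_feats,
        "genotype": geno_markers,
        "biomass": biomass_feats,
    }


def make_ground_truth(spec: DesignSpec) -> GroundTruth:
    """Draw allometry coefficients, drought multipliers and feature groups."""
    spec.validate()
    rng = substream(spec.seed, "truth")
    genos = spec.genotypes
    # allometric slopes in the plausible grass range; intercepts placed so
    # root weights land in a realistic fraction of shoot weights
    k = rng.uniform(0.16, 0.67, size=len(genos))
    ln_b = rng.normal(-1.6, 0.2, size=len(genos))
    # drought response: root response is diverse (strong increases through
    # mild decreases), shoot response milder
    root_mult = np.exp(rng.uniform(np.log(0.76), np.log(2.2), size=len(genos)))
    shoot_mult = np.exp(rng.uniform(np.log(0.70), np.log(1.2), size=len(genos)))
    alloc = _allocate_features(spec)
    truth = GroundTruth(
        n_features=spec.n_features,
        ln_b={g: float(v) for g, v in zip(genos, ln_b)},
        k={g: float(v) for g, v in zip(genos, k)},
        drought_shoot_mult={g: float(v) for g, v in zip(genos, shoot_mult)},
        drought_root_mult={g: float(v) for g, v in zip(genos, root_mult)},
        background_features=alloc["background"],
        tissue_marker_features=alloc["tissue"],
        genotype_marker_features=alloc["genotype"],
        drought_features=alloc["drought"],
        biomass_features=alloc["biomass"],
    )
    truth.validate_disjoint()
    return truth


def simulate_biomass(
    design: pd.DataFrame,
    truth: GroundTruth,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> BiomassTable:
    """Per-plant shoot and root dry weights under the allometric model.

    ln(root) = ln b_g + k_g * ln(shoot) + Normal(0, noise_sd); shoot drawn
    log-normally inside the 0.15-0.45 g band; drought multipliers act on
    the cell means (log-scale location shifts).
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = substream(seed, "biomass")
    plants = design.drop_duplicates("plant_id")[["plant_id", "genotype", "regime"]]
    plants = plants.reset_index(drop=True)
    n = len(plants)
    # ln-shoot centred at ~0.26 g; +-2sd spans roughly 0.15-0.45 g
    ln_shoot = rng.normal(np.log(0.26), 0.14, size=n)
    geno = plants["genotype"].to_numpy()
    regime = plants["regime"].to_numpy()
    k = np.array([truth.k[g] for g in geno])
    ln_b = np.array([truth.ln_b[g] for g in geno])
    drought = regime == "drought"
    ln_shoot = ln_shoot + np.where(
        drought, np.log([truth.drought_shoot_mult[g] for g in geno]), 0.0
    )
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    ln_root = ln_b + k * ln_shoot + eps
    ln_root = ln_root + np.where(
        drought, np.log([truth.drought_root_mult[g] for g in geno]), 0.0
    )
    shoot = np.exp(ln_shoot)
    root = np.exp(ln_root)
    assert np.all(shoot > 0) and np.all(root > 0)
    out = plants.assign(shoot_dw_g=shoot, root_dw_g=root)
    return BiomassTable(out)


def simulate_feature_table(
    design: pd.DataFrame,
    truth: GroundTruth,
    effects: EffectSizes | None = None,
    missing_rate: float = 0.03,
    outlier_rate: float = 0.002,
    seed: int = 0,
    biomass: BiomassTable | None = None,
    n_blanks: int = 6,
    outlier_factor: float = 100.0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Log-normal abundance table with planted effects, plus blank samples.

    Zeros and upper outliers are injected at the given rates and their
    coordinates recorded in ``truth``. Blank samples carry the background
    features at >= 50% of the sample-level abundance and all other
    features at a trace level, making background removal decidable.
    """
    effects = effects or EffectSizes()
    effects.validate()
    if not (0 <= missing_rate < 1 and 0 <= outlier_rate < 1):
        raise ConfigError("rates must lie in [0, 1)")
    rng = substream(seed, "features")
    meta = design.copy()
    n = len(meta)
    feat_names = (
        truth.background_features
        + truth.tissue_marker_features
        + truth.all_genotype_markers()
        + truth.drought_features
        + truth.biomass_features
    )
    # remaining pure-noise features complete the axis up to the largest id
    all_names = _complete_feature_axis(truth, feat_names)
    F = len(all_names)
    col_of = {f: j for j, f in enumerate(all_names)}

    mu = rng.normal(effects.baseline_mean, effects.baseline_sd, size=F)
    ln_v = mu[None, :] + rng.normal(0.0, effects.noise_sd, size=(n, F))

    above = (meta["tissue"] == "aboveground").to_numpy()
    drought = (meta["regime"] == "drought").to_numpy()
    geno = meta["genotype"].to_numpy()

    # tissue markers: half elevated aboveground, half belowground
    t_idx = np.array([col_of[f] for f in truth.tissue_marker_features])
    t_sign = np.where(np.arange(len(t_idx)) % 2 == 0, 1.0, -1.0)
    ln_v[np.ix_(above, t_idx)] += effects.tissue * t_sign
    # genotype signatures: additive shifts on each genotype's feature set
    for g, feats in truth.genotype_marker_features.items():
        g_idx = np.array([col_of[f] for f in feats])
        g_sign = np.where(np.arange(len(g_idx)) % 2 == 0, 1.0, -1.0)
        rows = geno == g
        ln_v[np.ix_(rows, g_idx)] += effects.genotype * g_sign
    # drought response: alternate sign; odd half tissue-specific (aboveground)
    d_idx = np.array([col_of[f] for f in truth.drought_features])
    d_sign = np.where(np.arange(len(d_idx)) % 2 == 0, 1.0, -1.0)
    specific = np.arange(len(d_idx)) % 2 == 1
    rows_all = drought
    rows_ag = drought & above
    ln_v[np.ix_(rows_all, d_idx[~specific])] += effects.regime * d_sign[~specific]
    ln_v[np.ix_(rows_ag, d_idx[specific])] += effects.regime * d_sign[specific]
    # biomass-linked features track the plant's biomass residual beyond
    # its genotype x regime cell mean
    if biomass is not None and truth.biomass_features:
        b_idx = np.array([col_of[f] for f in truth.biomass_features])
        bio = biomass.data.copy()
        bio["ln_total"] = np.log(bio["shoot_dw_g"] + bio["root_dw_g"])
        bio["resid"] = bio["ln_total"] - bio.groupby(["genotype", "regime"])[
            "ln_total"
        ].transform("mean")
        sd = bio["resid"].std(ddof=1)
        if sd > 0:
            bio["resid_z"] = bio["resid"] / sd
        else:
            bio["resid_z"] = 0.0
        resid_of = dict(zip(bio["plant_id"], bio["resid_z"]))
        rz = np.array([resid_of.get(p, 0.0) for p in meta["plant_id"]])
        ln_v[:, b_idx] += effects.biomass * rz[:, None]

    values = np.exp(ln_v)

    # blanks: background at 80% of baseline, everything else at a trace
    brng = substream(seed, "blanks")
    ln_blank = mu[None, :] + np.log(0.01) + brng.normal(0.0, 0.2, size=(n_blanks, F))
    bg_idx = np.array([col_of[f] for f in truth.background_features])
    ln_blank[:, bg_idx] = (
        mu[bg_idx][None, :] + np.log(0.8) + brng.normal(0.0, 0.2, size=(n_blanks, len(bg_idx)))
    )
    blanks = pd.DataFrame(
        np.exp(ln_blank),
        index=[f"blank_{i + 1}" for i in range(n_blanks)],
        columns=all_names,
    )

    # injected zeros then upper outliers (disjoint coordinates, and outliers
    # avoid background features which are dropped before outlier scoring)
    irng = substream(seed, "inject")
    truth.zero_cells = []
    truth.outlier_cells = []
    n_cells = n * F
    n_zero = int(round(missing_rate * n_cells))
    flat = irng.choice(n_cells, size=n_zero, replace=False) if n_zero else np.array([], int)
    zr, zc = np.unravel_index(flat, (n, F))
    values[zr, zc] = 0.0
    sample_ids = meta.index.to_numpy()
    truth.zero_cells = [(str(sample_ids[r]), all_names[c]) for r, c in zip(zr, zc)]
    zero_set = set(zip(zr.tolist(), zc.tolist()))

    n_out = int(round(outlier_rate * n_cells))
    eligible_cols = np.array(
        [j for j, f in enumerate(all_names) if f not in set(truth.background_features)]
    )
    # outliers avoid cell-features already holding a zero (a short cell lets
    # interpolated quartiles absorb the spike, making detection undecidable)
    cell_id = (
        meta["genotype"].astype(str)
        + "|" + meta["regime"].astype(str)
        + "|" + meta["tissue"].astype(str)
    ).to_numpy()
    cell_code = pd.factorize(cell_id)[0]
    blocked = {(cell_code[r], c) for r, c in zip(zr, zc)}
    placed = 0
    attempts = 0
    out_coords: list[tuple[int, int]] = []
    occupied: set[tuple[int, int]] = set()
    while placed < n_out and attempts < 50 * max(1, n_out):
        r = int(irng.integers(0, n))
        c = int(irng.choice(eligible_cols))
        attempts += 1
        key = (cell_code[r], c)
        if (r, c) in zero_set or key in blocked or key in occupied:
            continue
        values[r, c] *= outlier_factor
        out_coords.append((r, c))
        occupied.add(key)
        placed += 1
    truth.outlier_cells = [(str(sample_ids[r]), all_names[c]) for r, c in out_coords]

    table = FeatureTable(
        pd.DataFrame(values, index=meta.index, columns=all_names), meta
    )
    table.logged(step="simulate", seed=seed, n_samples=n, n_features=F,
                 missing_rate=missing_rate, outlier_rate=outlier_rate)
    return table, blanks


def _complete_feature_axis(truth: GroundTruth, planted: list[str]) -> list[str]:
    """Rebuild the full ordered feature axis (planted prefix + noise tail)."""
    width = len(planted[0]) - 1
    return [f"F{i + 1:0{width}d}" for i in range(truth.n_features)]


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    spec: DesignSpec
    design: pd.DataFrame
    truth: GroundTruth
    biomass: BiomassTable
    table: FeatureTable
    blanks: pd.DataFrame


def generate_study(
    spec: DesignSpec,
    effects: EffectSizes | None = None,
    missing_rate: float = 0.03,
    outlier_rate: float = 0.002,
    biomass_noise_sd: float = 0.15,
) -> StudyBundle:
    """Generate a full synthetic study from a single seed."""
    spec.validate()
    design = generate_design(spec)
    truth = make_ground_truth(spec)
    biomass = simulate_biomass(design, truth, noise_sd=biomass_noise_sd, seed=spec.seed)
    table, blanks = simulate_feature_table(
        design,
        truth,
        effects=effects,
        missing_rate=missing_rate,
        outlier_rate=outlier_rate,
        seed=spec.seed,
        biomass=biomass,
    )
    return StudyBundle(spec, design, truth, biomass, table, blanks)
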