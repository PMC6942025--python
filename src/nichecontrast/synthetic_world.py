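"""Virtual climate grids and virtual mosquito occurrences with known niches.

The synthetic world stands in for real gridded weather products and field
occurrence databases so that the whole pipeline — covariate extraction,
contrast-class training, temporal hold-out validation, habitat mapping —
can be exercised end to end with known ground truth.

The world is a stack of smooth random surfaces, one per weather variable,
on a km grid.  Each variable has a fixed spatial "geography" shared by all
years plus a year-specific smooth anomaly whose amplitude is the
inter-annual noise scale.  A species is a :class:`NicheSpec`: for each
variable a Gaussian (squared-exponential) response
``exp(-weight * ((value - optimum) / breadth)**2)``, combined
multiplicatively over variables.  Occurrence points are drawn over cells
with probability proportional to that suitability and jittered uniformly
within their cell; realized counts are Poisson around the configured
abundance.

The bundled scenario mirrors a four-species design — one invasive target
plus three natives with overlapping but distinct niches and strongly
unbalanced sample sizes (ratio roughly 5:20:3:1) — and records every
generating parameter for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .geodata_io import INVASIVE, NATIVE, OccurrenceRecord
from .grids import CANONICAL_VARIABLES, ClimateStack, GridGeometry

#: Per-variable climatology the smooth fields are scaled to:
#: name -> (mean, amplitude). Amplitude is the spatial standard deviation.
#: Temperatures in degC, precipitation sums in mm, drought index unitless.
VARIABLE_PROFILES: Mapping[str, tuple[float, float]] = {
    "T13": (8.5, 1.5),
    "T09": (13.5, 1.2),
    "T10": (9.0, 1.2),
    "T12": (1.0, 1.8),
    "P02": (45.0, 15.0),
    "P04": (50.0, 18.0),
    "P06": (75.0, 25.0),
    "D15": (12.0, 4.0),
}
_DEFAULT_PROFILE = (0.0, 1.0)


@dataclass(frozen=True)
class NicheResponse:
    """Gaussian response to one variable, in the variable's own units."""

    optimum: float
    breadth: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.breadth <= 0:
            raise ValueError("breadth must be positive")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


@dataclass(frozen=True)
class NicheSpec:
    """A virtual species: per-variable responses plus expected yearly count."""

    species_id: str
    responses: Mapping[str, NicheResponse]
    abundance: int

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")

    def suitability(self, values_by_var: Mapping[str, np.ndarray]) -> np.ndarray:
        """Multiplicative suitability at the given variable values."""
        missing = set(self.responses) - set(values_by_var)
        if missing:
            raise ValueError(
                f"niche {self.species_id!r} references variables absent "
                f"from the stack: {sorted(missing)}")
        out: np.ndarray | None = None
        for var, resp in self.responses.items():
            v = np.asarray(values_by_var[var], dtype=float)
            term = np.exp(-resp.weight * ((v - resp.optimum) / resp.breadth) ** 2)
            out = term if out is None else out * term
        if out is None:  # no responses: flat niche
            any_var = next(iter(values_by_var))
            out = np.ones_like(np.asarray(values_by_var[any_var], dtype=float))
        return out


@dataclass(frozen=True)
class WorldConfig:
    rows: int = 50
    cols: int = 50
    cell_size: float = 1.0  # km
    years: tuple[int, ...] = (2011, 2012, 2013, 2014, 2015)
    variables: tuple[str, ...] = CANONICAL_VARIABLES
    smoothness: float = 6.0  # gaussian_filter sigma, in cells
    noise_scale: float = 0.3  # inter-annual anomaly, as fraction of amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 4:
            raise ValueError("grid must have at least 4 cells")
        if not self.years:
            raise ValueError("years must be non-empty")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be nonnegative")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(rows=self.rows, cols=self.cols,
                            cell_size=self.cell_size)


def _smooth_field(rows: int, cols: int, sigma: float,
                  entropy: Sequence[int]) -> np.ndarray:
    """Standardized low-frequency random surface (zero mean, unit sd)."""
    rng = np.random.default_rng(np.random.SeedSequence(list(entropy)))
    white = rng.standard_normal((rows, cols))
    smooth = gaussian_filter(white, sigma=sigma, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # degenerate tiny grid
        return np.zeros((rows, cols))
    return (smooth - smooth.mean()) / sd


def generate_climate_stack(config: WorldConfig, year: int) -> ClimateStack:
    """Smooth per-variable surfaces for one year; bit-reproducible.

    Each variable is a fixed base geography (seeded by world seed and
    variable) plus a year-specific anomaly scaled by the inter-annual
    noise; zero noise makes all years identical.
    """
    if year not in config.years:
        raise ValueError(f"year {year} not in configured years {config.years}")
    layers: dict[str, np.ndarray] = {}
    for i, var in enumerate(config.variables):
        mean, amp = VARIABLE_PROFILES.get(var, _DEFAULT_PROFILE)
        base = _smooth_field(config.rows, config.cols, config.smoothness,
                             (config.seed, 1, i))
        if config.noise_scale > 0:
            anomaly = _smooth_field(config.rows, config.cols, config.smoothness,
                                    (config.seed, 2, i, year))
            fieldv = base + config.noise_scale * anomaly
        else:
            fieldv = base
        layers[var] = mean + amp * fieldv
    return ClimateStack(label=year, geometry=config.geometry, layers=layers)


def generate_occurrences(config: WorldConfig, niche: NicheSpec,
                         stack: ClimateStack, seed: int,
                         count: int | None = None) -> list[OccurrenceRecord]:
    """Sample occurrence points for one species in one year's world.

    Cells are drawn (with replacement) with probability proportional to the
    niche's multiplicative suitability at the cell's values; each point is
    jittered uniformly within its cell.  The realized count is
    Poisson(abundance) unless ``count`` pins it exactly.
    """
    geom = stack.geometry
    values_by_var = {v: stack.layers[v] for v in stack.layers}
    suit = niche.suitability(values_by_var).astype(float)
    valid = stack.valid_mask()
    suit = np.where(valid, suit, 0.0)
    total = suit.sum()
    if total <= 0:
        raise ValueError("niche suitability is zero on every valid cell")

    rng = np.random.default_rng(np.random.SeedSequence([seed, abs(hash_str(
        niche.species_id)) % (2 ** 31), int(stack.label)]))
    n = int(count) if count is not None else int(rng.poisson(niche.abundance))
    flat_p = (suit / total).ravel()
    cells = rng.choice(flat_p.size, size=n, replace=True, p=flat_p)
    u = rng.random(n)
    v = rng.random(n)
    records: list[OccurrenceRecord] = []
    for k, cell in enumerate(cells):
        row, col = divmod(int(cell), geom.cols)
        x = geom.x0 + (col + u[k]) * geom.cell_size
        y = geom.y0 - (row + v[k]) * geom.cell_size
        records.append(OccurrenceRecord(niche.species_id, int(stack.label), x, y))
    return records


def hash_str(s: str) -> int:
    """Deterministic small hash of a string (process-independent)."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2 ** 31)
    return h


# ---------------------------------------------------------------------------
# The bundled four-species scenario

INVASIVE_SPECIES = "Ae_japonicus"
NATIVE_SPECIES = ("Ae_vexans", "Ae_geniculatus", "An_daciae")

#: Per-species niche design, expressed in field-standardized units:
#: variable -> (optimum offset from the variable mean in amplitudes,
#:              breadth in amplitudes, weight).  The invasive species sits
#: on the warm/wet side of every variable while the three natives occupy
#: the opposite flank with broader or shifted responses, giving the
#: overlapping-but-distinct class distributions the contrast-class design
#: assumes.
_SCENARIO_NICHES: Mapping[str, Mapping[str, tuple[float, float, float]]] = {
    INVASIVE_SPECIES: {
        "T13": (+1.2, 1.2, 0.8), "T09": (+1.0, 1.2, 0.7),
        "T10": (+0.9, 1.2, 0.7), "T12": (+1.0, 1.2, 0.7),
        "P02": (+1.2, 1.2, 0.8), "P04": (+1.2, 1.2, 0.8),
        "P06": (+1.1, 1.2, 0.8), "D15": (-1.1, 1.2, 0.8),
    },
    "Ae_vexans": {
        "T13": (-0.5, 1.6, 0.5), "T09": (-0.4, 1.6, 0.4),
        "T10": (-0.4, 1.6, 0.4), "T12": (-0.3, 1.6, 0.4),
        "P02": (-0.6, 1.5, 0.5), "P04": (-0.6, 1.5, 0.5),
        "P06": (-0.5, 1.5, 0.5), "D15": (+0.6, 1.5, 0.5),
    },
    "Ae_geniculatus": {
        "T13": (-0.3, 1.4, 0.5), "T09": (-0.6, 1.4, 0.5),
        "T10": (-0.3, 1.4, 0.5), "T12": (-0.6, 1.4, 0.5),
        "P02": (-0.4, 1.4, 0.5), "P04": (-0.8, 1.4, 0.5),
        "P06": (-0.6, 1.4, 0.5), "D15": (+0.4, 1.4, 0.5),
    },
    "An_daciae": {
        "T13": (-0.6, 1.3, 0.6), "T09": (-0.3, 1.3, 0.5),
        "T10": (-0.6, 1.3, 0.5), "T12": (-1.2, 1.3, 0.7),
        "P02": (-0.9, 1.3, 0.6), "P04": (-0.4, 1.3, 0.5),
        "P06": (-0.9, 1.3, 0.6), "D15": (+0.9, 1.3, 0.6),
    },
}

#: Expected occurrence counts per species per training year; over the four
#: training years these total 508 : 2056 : 322 : 102 (ratio ~ 5:20:3:1),
#: the strongly unbalanced design the subsampling cap exists for.
SCENARIO_YEARLY_ABUNDANCE: Mapping[str, int] = {
    INVASIVE_SPECIES: 127,
    "Ae_vexans": 514,
    "Ae_geniculatus": 80,
    "An_daciae": 26,
}

#: Exact record counts of the reference study design: per-species training
#: totals over 2011-2014, and the 2015 temporal hold-out (308 invasive,
#: 115 native test points; the native split across species is this
#: package's choice, proportional to training abundance).
SUPPLEMENT_TRAIN_COUNTS: Mapping[str, int] = {
    INVASIVE_SPECIES: 508, "Ae_vexans": 2056,
    "Ae_geniculatus": 322, "An_daciae": 102,
}
SUPPLEMENT_TEST_COUNTS: Mapping[str, int] = {
    INVASIVE_SPECIES: 308, "Ae_vexans": 77,
    "Ae_geniculatus": 25, "An_daciae": 13,
}
TRAIN_YEARS = (2011, 2012, 2013, 2014)
TEST_YEAR = 2015


def species_role_map() -> dict[str, str]:
    roles = {INVASIVE_SPECIES: INVASIVE}
    roles.update({s: NATIVE for s in NATIVE_SPECIES})
    return roles


def make_paperlike_scenario(seed: int,
                            separation: float = 1.0,
                            ) -> tuple[WorldConfig, list[NicheSpec], dict]:
    """Four-species scenario: one invasive, three natives, known truth.

    ``separation`` scales every niche optimum's offset from the variable
    mean; 1.0 is the default overlapping-but-distinct design, 0.0 makes all
    four niches identical (the no-skill null).

    Returns the world config, the four niche specs (invasive first) and a
    truth record holding every generating parameter.
    """
    config = WorldConfig(seed=seed)
    niches: list[NicheSpec] = []
    for species, design in _SCENARIO_NICHES.items():
        responses = {}
        for var, (off, breadth_amp, weight) in design.items():
            mean, amp = VARIABLE_PROFILES.get(var, _DEFAULT_PROFILE)
            responses[var] = NicheResponse(
                optimum=mean + separation * off * amp,
                breadth=breadth_amp * amp,
                weight=weight,
            )
        niches.append(NicheSpec(
            species_id=species, responses=responses,
            abundance=SCENARIO_YEARLY_ABUNDANCE[species]))
    truth = {
        "invasive_species": INVASIVE_SPECIES,
        "native_species": list(NATIVE_SPECIES),
        "separation": separation,
        "config": config,
        "niches": {n.species_id: n for n in niches},
        "roles": species_role_map(),
        "train_years": list(TRAIN_YEARS),
        "test_year": TEST_YEAR,
    }
    return config, niches, truth


def _split_count(total: int, n_parts: int) -> list[int]:
    base, rem = divmod(total, n_parts)
    return [base + (1 if i < rem else 0) for i in range(n_parts)]


def make_synthetic_supplement(seed: int) -> dict:
    """Synthetic stand-in for the study's per-species occurrence tables.

    Generates the full five-year world and draws occurrences with *exact*
    per-species totals — 508/2056/322/102 over the four training years and
    308 invasive + 115 native points in the hold-out year — so that
    record-count contracts can be checked exactly.  All weather values are
    synthetic; only the sampling design mirrors the reference study.

    Returns a dict with keys ``config``, ``niches``, ``truth``,
    ``stacks`` (year -> ClimateStack) and ``records`` (species ->
    list[OccurrenceRecord]).
    """
    config, niches, truth = make_paperlike_scenario(seed)
    stacks = {yr: generate_climate_stack(config, yr) for yr in config.years}
    records: dict[str, list[OccurrenceRecord]] = {}
    for niche in niches:
        per_year = _split_count(SUPPLEMENT_TRAIN_COUNTS[niche.species_id],
                                len(TRAIN_YEARS))
        recs: list[OccurrenceRecord] = []
        for yr, n in zip(TRAIN_YEARS, per_year):
            recs.extend(generate_occurrences(config, niche, stacks[yr],
                                             seed=seed, count=n))
        recs.extend(generate_occurrences(
            config, niche, stacks[TEST_YEAR], seed=seed,
            count=SUPPLEMENT_TEST_COUNTS[niche.species_id]))
        records[niche.species_id] = recs
    return {"config": config, "niches": niches, "truth": truth,
            "stacks": stacks, "records": records}
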