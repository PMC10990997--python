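"""Synthetic study generator.

Emulates the full blood-flow experiment end to end so that every
pipeline stage can be exercised without any animal data: per-animal
ground-truth regional flows drawn around group means with a
strain × treatment structure, a gamma-variate arterial input sampled
every 3 s for 60 s, terminal tissue concentrations computed through the
forward kinetic model, a synthetic linear film response mapping
activity to optical density, eight calibration standards log-spaced
over 40–1069 nCi/g, ≥8 noisy density readings per region, and a
Western-blot densitometry fixture (n = 3 per group).

Randomness is fully seeded: each animal draws from its own generator
keyed by (study seed, group index, animal index), so enlarging a group
or adding groups never perturbs previously generated animals.  With
``between_animal_cv = 0`` and ``od_noise_sd = 0`` the downstream
calibrate → invert pipeline recovers every true flow to numerical
tolerance, because the simulated (noisy) arterial curve is recorded and
used for inversion exactly as a real measured input function would be.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationStandard
from .errors import GeneratorError, ValidationError
from .kinetics import REGIONS, ArterialCurve, KineticParams, forward_tissue_concentration

__all__ = [
    "StudyDesign",
    "AnimalRecord",
    "SimulatedStudy",
    "reference_study_design",
    "simulate_arterial_curve",
    "simulate_study",
    "simulate_blots",
    "write_study",
]

STRAINS = ("control", "mutant")
TREATMENTS = ("vehicle", "inhibitor")

#: Range spanned by the precalibrated standards (nCi/g).
STANDARDS_RANGE = (40.0, 1069.0)
N_STANDARDS = 8

#: Synthetic film response: OD per nCi/g of tissue activity.  A linear
#: response keeps the interpolating calibration exact, so calibration
#: error never masks kinetic error in recovery tests.
OD_PER_NCI_G = 0.001

#: Mean regional flows of the control-vehicle group, ml·g⁻¹·min⁻¹
#: (plausible values for isoflurane-anesthetized young rats).
CONTROL_FLOWS = {"cortex": 1.10, "hippocampus": 0.95, "cerebellum": 1.00, "pons": 0.85}

#: Group-mean flow ratios relative to control-vehicle, per region.
#: Mutant-vehicle cortex +32% and hippocampus +15%; the inhibitor
#: restores mutant flow to control level in those regions and produces
#: only a small (non-significant at n = 8, cv = 0.10) reduction elsewhere.
GROUP_RATIOS = {
    ("control", "vehicle"): {r: 1.00 for r in REGIONS},
    ("control", "inhibitor"): {r: 0.95 for r in REGIONS},
    ("mutant", "vehicle"): {"cortex": 1.32, "hippocampus": 1.15,
                            "cerebellum": 1.00, "pons": 1.00},
    ("mutant", "inhibitor"): {"cortex": 1.00, "hippocampus": 1.00,
                              "cerebellum": 0.97, "pons": 0.97},
}


@dataclass
class StudyDesign:
    """Layout and noise model of one simulated study."""

    group_mean_flow: Mapping[tuple[str, str, str], float]
    strains: tuple[str, ...] = STRAINS
    treatments: tuple[str, ...] = TREATMENTS
    regions: tuple[str, ...] = REGIONS
    n_per_group: int = 8
    between_animal_cv: float = 0.10
    od_noise_sd: float = 0.002         # OD units (~2 nCi/g at the film response)
    arterial_noise_cv: float = 0.05    # multiplicative log-normal, per sample
    peak_conc: float = 600.0           # nCi/ml
    rise_time_s: float = 60.0
    n_readings: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.between_animal_cv < 0 or self.od_noise_sd < 0 or self.arterial_noise_cv < 0:
            raise ValidationError("noise parameters must be non-negative")
        for key in ((s, t, r) for s in self.strains for t in self.treatments
                    for r in self.regions):
            if key not in self.group_mean_flow:
                raise ValidationError(f"group_mean_flow missing entry {key}")
            if self.group_mean_flow[key] <= 0:
                raise ValidationError(f"group mean flow for {key} must be > 0")


def reference_study_design(
    seed: int = 0,
    n_per_group: int = 8,
    between_animal_cv: float = 0.10,
    **overrides,
) -> StudyDesign:
    """The study-mirror design: 4 groups × 8 animals with the observed
    group-ratio structure (cortex +32%, hippocampus +15% in the
    vehicle-treated mutants; inhibitor restores mutants toward control)."""
    means = {
        (s, t, r): CONTROL_FLOWS[r] * GROUP_RATIOS[(s, t)][r]
        for s in STRAINS for t in TREATMENTS for r in REGIONS
    }
    return StudyDesign(group_mean_flow=means, seed=seed, n_per_group=n_per_group,
                       between_animal_cv=between_animal_cv, **overrides)


def simulate_arterial_curve(
    rng_or_seed,
    peak_conc: float = 600.0,
    rise_time_s: float = 60.0,
    noise_cv: float = 0.0,
    *,
    duration_s: float = 60.0,
    n_samples: int = 21,
) -> ArterialCurve:
    """Gamma-variate arterial input sampled every 3 s for 60 s.

    The noise-free shape is ``C_A(t) = peak·(t/rise)·e^{1−t/rise}``
    (0 at t = 0, maximum ``peak`` at t = rise); per-sample multiplicative
    log-normal noise with coefficient of variation ``noise_cv`` is applied
    on top.
    """
    if peak_conc <= 0:
        raise ValidationError("peak concentration must be > 0")
    if not (0 < rise_time_s <= duration_s):
        raise ValidationError("rise time must be in (0, duration]")
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    t = np.linspace(0.0, duration_s, n_samples)
    conc = peak_conc * (t / rise_time_s) * np.exp(1.0 - t / rise_time_s)
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        conc = conc * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=t.size)
    return ArterialCurve(times=t, concentrations=conc)


@dataclass
class AnimalRecord:
    """Everything simulated for one subject, ground truth included."""

    animal_id: str
    strain: str
    treatment: str
    true_flows: dict[str, float]                 # region -> ml·g⁻¹·min⁻¹
    curve: ArterialCurve
    tissue_conc: dict[str, float]                # region -> nCi/g (pre-noise truth)
    od_readings: dict[str, np.ndarray]           # region -> noisy OD readings


@dataclass
class SimulatedStudy:
    """A full simulated study plus the pipeline-dialect input tables."""

    design: StudyDesign
    params: KineticParams
    records: list[AnimalRecord]
    tables: dict[str, pd.DataFrame]  # arterial, standards, roi, animals, truth


def _standards_table() -> pd.DataFrame:
    activities = np.geomspace(*STANDARDS_RANGE, N_STANDARDS)
    return pd.DataFrame({
        "standard_id": [f"std{i + 1}" for i in range(N_STANDARDS)],
        "activity_nci_g": activities,
        "od": activities * OD_PER_NCI_G,
    })


def standards_from_table(table: pd.DataFrame) -> list[CalibrationStandard]:
    return [CalibrationStandard(activity=row.activity_nci_g, optical_density=row.od)
            for row in table.itertuples()]


def simulate_study(
    design: StudyDesign, params: Optional[KineticParams] = None
) -> SimulatedStudy:
    """Simulate every animal of the design and assemble the input tables.

    Per animal: true regional flows ~ Normal(group mean, cv·mean)
    truncated at 0; one arterial curve; tissue concentration from the
    forward model driven by the *recorded* curve; region OD readings as
    the film response of that concentration plus additive Gaussian noise.
    """
    params = params or KineticParams()
    lo, hi = STANDARDS_RANGE
    records: list[AnimalRecord] = []
    rows_arterial, rows_roi, rows_animals, rows_truth = [], [], [], []

    groups = [(s, t) for s in design.strains for t in design.treatments]
    for gi, (strain, treatment) in enumerate(groups):
        for j in range(design.n_per_group):
            rng = np.random.default_rng([design.seed % 2**31, gi, j])
            animal_id = f"{strain}-{treatment}-{j + 1:02d}"
            flows = {}
            for region in design.regions:
                mu = design.group_mean_flow[(strain, treatment, region)]
                for _ in range(100):
                    f = rng.normal(mu, design.between_animal_cv * mu)
                    if f > 0:
                        break
                else:  # pragma: no cover - cv would have to be enormous
                    raise GeneratorError(f"cannot draw a positive flow for {animal_id}")
                flows[region] = float(f)
            curve = simulate_arterial_curve(
                rng, design.peak_conc, design.rise_time_s, design.arterial_noise_cv
            )
            tissue, readings = {}, {}
            for region in design.regions:
                ci = forward_tissue_concentration(flows[region], curve, params)
                if not (lo <= ci <= hi):
                    raise GeneratorError(
                        f"tissue concentration {ci:.1f} nCi/g for {animal_id} "
                        f"{region} falls outside the standards range "
                        f"[{lo}, {hi}]; widen the standards or rescale the "
                        "arterial peak / group mean flows"
                    )
                od_true = ci * OD_PER_NCI_G
                ods = od_true + rng.normal(0.0, design.od_noise_sd, design.n_readings)
                tissue[region] = float(ci)
                readings[region] = ods
                rows_roi += [{"animal_id": animal_id, "region": region, "od": od}
                             for od in ods]
                rows_truth.append({"animal_id": animal_id, "strain": strain,
                                   "treatment": treatment, "region": region,
                                   "flow_ml_g_min": flows[region],
                                   "tissue_nci_g": tissue[region]})
            rows_arterial += [{"animal_id": animal_id, "time_s": t,
                               "conc_nci_ml": c}
                              for t, c in zip(curve.times, curve.concentrations)]
            rows_animals.append({"animal_id": animal_id, "strain": strain,
                                 "treatment": treatment})
            records.append(AnimalRecord(animal_id, strain, treatment, flows,
                                        curve, tissue, readings))

    tables = {
        "arterial": pd.DataFrame(rows_arterial),
        "standards": _standards_table(),
        "roi": pd.DataFrame(rows_roi),
        "animals": pd.DataFrame(rows_animals),
        "truth": pd.DataFrame(rows_truth),
    }
    return SimulatedStudy(design=design, params=params, records=records, tables=tables)


def simulate_blots(
    seed: int,
    group_effects: Optional[Mapping] = None,
    *,
    markers: tuple[str, ...] = ("pS6-S240/244", "pAkt-S473"),
    n_per_group: int = 3,
    noise_cv: float = 0.10,
) -> pd.DataFrame:
    """Western-blot densitometry fixture: phospho and total signals.

    ``group_effects`` multiplies the phospho/total ratio per
    (strain, treatment) group — either one mapping applied to every
    marker, or a mapping ``marker -> {(strain, treatment): multiplier}``.
    Signals are log-normal around 1 (arbitrary densitometry units) with
    coefficient of variation ``noise_cv``; a loading-control signal is
    included.  Returns the tidy blot table dialect.
    """
    def effect(marker: str, group: tuple[str, str]) -> float:
        if group_effects is None:
            return 1.0
        nested = isinstance(next(iter(group_effects.values()), None), Mapping)
        table = group_effects.get(marker, {}) if nested else group_effects
        return float(table.get(group, 1.0))

    sigma = float(np.sqrt(np.log1p(noise_cv**2))) if noise_cv > 0 else 0.0
    rows = []
    groups = [(s, t) for s in STRAINS for t in TREATMENTS]
    for gi, (strain, treatment) in enumerate(groups):
        for j in range(n_per_group):
            rng = np.random.default_rng([seed % 2**31, 1000 + gi, j])
            animal_id = f"blot-{strain}-{treatment}-{j + 1}"
            loading = float(rng.lognormal(0.0, sigma)) if sigma else 1.0
            for marker in markers:
                mult = effect(marker, (strain, treatment))
                if mult <= 0:
                    raise ValidationError("group effect multipliers must be > 0")
                total = float(rng.lognormal(0.0, sigma)) if sigma else 1.0
                ratio_noise = float(rng.lognormal(0.0, sigma)) if sigma else 1.0
                rows.append({
                    "animal_id": animal_id, "strain": strain,
                    "treatment": treatment, "marker": marker,
                    "phospho": total * mult * ratio_noise,
                    "total": total, "loading_control": loading,
                })
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write the study's input files plus design.yaml and a manifest.

    Files: ``arterial.csv, standards.csv, roi.csv, animals.csv,
    truth.csv, design.yaml, manifest.json``.  The manifest records the
    seed, a hash of the design, and a sha256 checksum per file, so two
    runs with the same seed are byte-identical and verifiable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.10g"
    for name, table in study.tables.items():
        table.to_csv(outdir / f"{name}.csv", index=False, float_format=float_fmt)

    design_doc = {
        "seed": study.design.seed,
        "n_per_group": study.design.n_per_group,
        "strains": list(study.design.strains),
        "treatments": list(study.design.treatments),
        "regions": list(study.design.regions),
        "between_animal_cv": study.design.between_animal_cv,
        "od_noise_sd": study.design.od_noise_sd,
        "arterial_noise_cv": study.design.arterial_noise_cv,
        "peak_conc": study.design.peak_conc,
        "rise_time_s": study.design.rise_time_s,
        "group_mean_flow": {
            f"{s}/{t}/{r}": v for (s, t, r), v in sorted(study.design.group_mean_flow.items())
        },
        "kinetics": {
            "lambda": study.params.partition_coefficient,
            "m": study.params.m,
            "decap_time_s": study.params.decapitation_time_s,
        },
    }
    (outdir / "design.yaml").write_text(yaml.safe_dump(design_doc, sort_keys=True))

    design_hash = hashlib.sha256(
        json.dumps(design_doc, sort_keys=True).encode()
    ).hexdigest()
    files = sorted(p.name for p in outdir.iterdir()
                   if p.suffix in (".csv", ".yaml"))
    manifest = {
        "seed": study.design.seed,
        "design_sha256": design_hash,
        "files": {name: _sha256(outdir / name) for name in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
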