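"""Reproducible end-to-end runs: simulate -> quantify -> distribution ->
colocalize -> fit-binding.

A :class:`RunConfig` (YAML-serialisable) fixes every stage parameter
and a single global seed; per-stage generators receive independent
streams spawned deterministically from it, so re-running the same
config and seed reproduces identical numerical outputs.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import stau_rnaloc
from stau_rnaloc import io as srio
from stau_rnaloc.annotation import OocyteAnnotation
from stau_rnaloc.binding import select_model
from stau_rnaloc.coloc import coloc_by_bin, expected_coloc, nn_pairs, scaling_fit
from stau_rnaloc.distribution import compare_groups, oocyte_descriptors
from stau_rnaloc.errors import InvalidParameterError
from stau_rnaloc.quantify import UnitIntensityCalibrator
from stau_rnaloc.synthetic import (
    NoiseSpec,
    make_oocyte,
    simulate_binding_curve,
    simulate_protein_particles,
    simulate_rna_spots,
)


def _default_genotypes() -> dict:
    # wild-type-like posterior localization with strong per-copy scaling,
    # a null with neither, and a binding-mutant with weak scaling
    return {
        "wt": {"frac_posterior": 0.8, "frac_anterior": 0.0, "frac_bound": 0.8, "slope": 2.0},
        "stau_null": {"frac_posterior": 0.05, "frac_anterior": 0.3, "frac_bound": 0.2, "slope": 0.2},
        "mutant": {"frac_posterior": 0.2, "frac_anterior": 0.2, "frac_bound": 0.4, "slope": 0.5},
    }


def _default_binding() -> list[dict]:
    return [
        {
            "name": "two_site_demo",
            "model": "two_site",
            "params": {"kd1": 18.0, "kd2": 2000.0, "rmax1": 50.0, "rmax2": 50.0},
            "conc_min_nm": 1.0,
            "conc_max_nm": 1000.0,
            "n_conc": 12,
            "noise_sd": 0.5,
        }
    ]


@dataclass
class RunConfig:
    """All stage parameters plus the single global seed."""

    out_dir: str = "run_output"
    seed: int = 0
    log_level: str = "INFO"
    # simulate
    n_oocytes_per_genotype: int = 6
    n_mrnps: int = 400
    oocyte_length_um: float = 100.0
    oocyte_width_um: float = 50.0
    pole_spread_um: float = 2.0
    unit_intensity: float = 100.0
    intensity_cv: float = 0.2
    copy_geometric_p: float = 0.8
    n_background_particles: int = 100
    protein_jitter_um: float = 0.1
    n_calibration_spots: int = 3000
    genotypes: dict = field(default_factory=_default_genotypes)
    # quantify
    min_normalized: float = 0.5
    # distribution
    reference_genotype: str = "stau_null"
    alpha: float = 0.05
    enrichment_fold: float = 2.0
    # colocalize
    coloc_radius_um: float = 0.3
    n_rand: int = 50
    # binding
    binding: list = field(default_factory=_default_binding)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int
    timings_s: dict
    warnings: list
    outputs: list

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    # independent per-stage streams derived from the global seed
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages as configured; fail fast with stage context."""
    if config.reference_genotype not in config.genotypes:
        raise InvalidParameterError(
            f"reference genotype {config.reference_genotype!r} is not among the "
            f"configured genotypes {sorted(config.genotypes)}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    timings: dict[str, float] = {}
    warnings_log: list[str] = []
    outputs: list[str] = []

    def _write(obj, path: Path, writer) -> None:
        writer(obj, path)
        outputs.append(str(path.relative_to(out)))

    # ---- stage 1: simulate ------------------------------------------------
    t0 = time.perf_counter()
    rng = np.random.default_rng(seeds[0])
    manifest_rows = []
    truths = {}
    for genotype, spec in config.genotypes.items():
        for i in range(config.n_oocytes_per_genotype):
            oid = f"{genotype}_{i:02d}"
            sub = int(rng.integers(0, 2**31))
            annot = make_oocyte(
                config.oocyte_length_um, config.oocyte_width_um, seed=sub
            )
            noise = NoiseSpec(cv=config.intensity_cv, seed=sub)
            spots, truth = simulate_rna_spots(
                annot,
                n_mrnps=config.n_mrnps,
                copy_geometric_p=config.copy_geometric_p,
                frac_posterior=spec["frac_posterior"],
                frac_anterior=spec.get("frac_anterior", 0.0),
                pole_spread=config.pole_spread_um,
                unit_intensity=config.unit_intensity,
                noise=noise,
            )
            particles, truth = simulate_protein_particles(
                spots,
                truth,
                frac_bound=spec["frac_bound"],
                slope=spec["slope"] * config.unit_intensity,
                jitter=config.protein_jitter_um,
                n_background=config.n_background_particles,
                noise=noise.with_seed(sub + 1),
                annot=annot,
            )
            spots_path = out / f"spots_rna_{oid}.csv"
            prot_path = out / f"spots_protein_{oid}.csv"
            annot_path = out / f"annot_{oid}.json"
            _write(spots, spots_path, srio.write_spot_table)
            _write(particles, prot_path, srio.write_spot_table)
            _write(annot, annot_path, srio.write_annotation)
            srio.write_json(
                {
                    "unit_intensity": truth.unit_intensity,
                    "protein_slope": truth.protein_slope,
                    "rna": truth.rna.to_dict(orient="list"),
                    "protein": truth.protein.to_dict(orient="list"),
                },
                out / f"truth_{oid}.json",
            )
            outputs.append(f"truth_{oid}.json")
            truths[oid] = truth
            manifest_rows.append(
                {
                    "oocyte_id": oid,
                    "genotype": genotype,
                    "stage": 9,
                    "spots_path": spots_path.name,
                    "protein_path": prot_path.name,
                    "annot_path": annot_path.name,
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    outputs.append("manifest.csv")
    # calibration distribution (single-molecule dominated, nurse-cell analogue)
    calib_annot = make_oocyte(
        config.oocyte_length_um, config.oocyte_width_um, seed=seeds[1]
    )
    calib_spots, _ = simulate_rna_spots(
        calib_annot,
        n_mrnps=config.n_calibration_spots,
        copy_geometric_p=config.copy_geometric_p,
        unit_intensity=config.unit_intensity,
        noise=NoiseSpec(cv=config.intensity_cv, seed=seeds[1]),
    )
    _write(calib_spots, out / "calibration_spots.csv", srio.write_spot_table)
    timings["simulate"] = time.perf_counter() - t0

    # ---- stage 2: quantify ------------------------------------------------
    t0 = time.perf_counter()
    calibrator = UnitIntensityCalibrator(
        min_normalized=config.min_normalized, random_state=seeds[2]
    ).fit(calib_spots["intensity"])
    srio.write_json(calibrator.calibration_.to_dict(), out / "calibration.json")
    outputs.append("calibration.json")
    copy_tables = {}
    for row in manifest.itertuples():
        spots = srio.read_spot_table(out / row.spots_path)
        copy_tables[row.oocyte_id] = calibrator.transform(spots)
    pd.concat(
        [t.assign(oocyte_id=oid) for oid, t in copy_tables.items()], ignore_index=True
    ).to_csv(out / "copy_numbers.csv", index=False)
    outputs.append("copy_numbers.csv")
    timings["quantify"] = time.perf_counter() - t0

    # ---- stage 3: distribution -------------------------------------------
    t0 = time.perf_counter()
    desc_rows = []
    for row in manifest.itertuples():
        spots = srio.read_spot_table(out / row.spots_path)
        annot = srio.read_annotation(out / row.annot_path)
        desc = oocyte_descriptors(spots, annot, enrichment=config.enrichment_fold)
        desc_rows.append({"oocyte_id": row.oocyte_id, "genotype": row.genotype, **desc})
    descriptors = pd.DataFrame(desc_rows)
    descriptors.to_csv(out / "descriptors.csv", index=False)
    outputs.append("descriptors.csv")
    stats_out = {}
    for metric in ("com_ap", "posterior_fraction"):
        groups = {
            g: grp[metric].to_numpy() for g, grp in descriptors.groupby("genotype")
        }
        stats_out[metric] = compare_groups(
            groups, reference=config.reference_genotype, alpha=config.alpha
        ).to_dict()
    srio.write_json(stats_out, out / "distribution_stats.json")
    outputs.append("distribution_stats.json")
    timings["distribution"] = time.perf_counter() - t0

    # ---- stage 4: colocalize ---------------------------------------------
    t0 = time.perf_counter()
    coloc_frames = []
    scaling_rows = []
    rng_coloc = np.random.default_rng(seeds[3])
    for row in manifest.itertuples():
        rna = srio.read_spot_table(out / row.spots_path)
        protein = srio.read_spot_table(out / row.protein_path)
        annot = srio.read_annotation(out / row.annot_path)
        copies = copy_tables[row.oocyte_id]
        rna_used = rna[rna["id"].isin(copies["id"])].reset_index(drop=True)
        pairing = nn_pairs(rna_used, protein, r_um=config.coloc_radius_um)
        bins = copies.set_index("id").loc[rna_used["id"], "bin"].to_numpy()
        expected = expected_coloc(
            rna_used,
            protein,
            annot,
            r_um=config.coloc_radius_um,
            n_rand=config.n_rand,
            seed=int(rng_coloc.integers(0, 2**31)),
            bins=bins,
        )
        result = coloc_by_bin(pairing, copies, expected)
        coloc_frames.append(
            result.assign(oocyte_id=row.oocyte_id, genotype=row.genotype)
        )
        # protein intensity per colocalized pair, for the scaling fit;
        # intensities are normalised by the calibrated single-molecule unit
        prot_int = protein.set_index("id")["intensity"]
        merged = pairing[pairing["colocalized"]].merge(
            copies[["id", "bin", "normalized"]], left_on="rna_id", right_on="id"
        )
        for rec in merged.itertuples():
            scaling_rows.append(
                {
                    "genotype": row.genotype,
                    "copy_number": round(rec.normalized),
                    "protein_intensity": prot_int.loc[rec.nn_id]
                    / calibrator.unit_intensity_,
                }
            )
    pd.concat(coloc_frames, ignore_index=True).to_csv(
        out / "colocalization.csv", index=False
    )
    outputs.append("colocalization.csv")
    scaling_data = pd.DataFrame(scaling_rows)
    scaling = scaling_fit(scaling_data, alpha=config.alpha)
    srio.write_json(scaling.to_dict(), out / "scaling.json")
    outputs.append("scaling.json")
    timings["colocalize"] = time.perf_counter() - t0

    # ---- stage 5: fit-binding --------------------------------------------
    t0 = time.perf_counter()
    binding_out = {}
    for i, spec in enumerate(config.binding):
        conc = np.geomspace(spec["conc_min_nm"], spec["conc_max_nm"], spec["n_conc"])
        curve = simulate_binding_curve(
            spec["model"],
            spec["params"],
            conc,
            noise_sd=spec.get("noise_sd", 0.0),
            seed=seeds[4] + i,
        )
        srio.write_curve(curve, out / f"curve_{spec['name']}.csv")
        outputs.append(f"curve_{spec['name']}.csv")
        selector = select_model(curve, seed=seeds[5] + i)
        binding_out[spec["name"]] = {
            "generating": {"model": spec["model"], "params": spec["params"]},
            "fit": selector.result(),
        }
    srio.write_json(binding_out, out / "binding_fits.json")
    outputs.append("binding_fits.json")
    timings["fit_binding"] = time.perf_counter() - t0

    report = RunReport(
        version=stau_rnaloc.__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        timings_s={k: round(v, 3) for k, v in timings.items()},
        warnings=warnings_log,
        outputs=outputs,
    )
    srio.write_json(report.to_dict(), out / "run_report.json")
    config.to_yaml(out / "config.yaml")
    return report
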