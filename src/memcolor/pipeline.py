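"""End-to-end orchestration: simulate, decode, test, report.

``run_pipeline`` executes the full synthetic study for three simulated
regions (a V4-like and a TEO-like color patch and a temporal-pole-like
familiarity region) and reproduces the structure of the main decoding
figure: exemplar-split memory-color decoding (with and without the
confound-excluded fold cases), grating-to-object transfer decoding,
true/false decoding, 4-way object-identity decoding and the period x
true/false interaction test.  ROI-level inference uses run-level
label-permutation tests (calibrated even when fold schemes reuse test
samples) with one BH-FDR family per report.  Everything is reproducible
from (config, seed): rerunning the same configuration yields
bit-identical beta-level data and reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decoding import (
    confound_excluded_cases,
    exemplar_split_folds,
    leave_one_run_out,
    permute_conditions_within_runs,
    run_exemplar_split,
    transfer_decode,
)
from .designs import (
    EXP1, EXP2, EXP3, EXP3_OBJECTS, IDENTITY_CONDITIONS, CONDITIONS,
    make_design,
)
from .patterns import PatternMatrix
from .stats import (
    StatResult, bh_fdr, cohens_d, interaction_period_truefalse, permutation_test,
)
from .synth import (
    DEFAULT_SHAPE_SIMILARITY, GeneratorParams, GroundTruth, PROFILES,
    make_design_set, plant_codes, simulate_betas, simulate_timeseries,
)
from . import io as mio

log = logging.getLogger("memcolor")

#: the red/green exemplar layout used for 2-way memory-color decoding
RED_GREEN_CATEGORIES = {
    "red": ["strawberry", "watermelon"],
    "green": ["cabbage", "kiwi"],
}

TRUEFALSE_LABELS = {
    c: ("true" if c.endswith("_true") else "false") for c in CONDITIONS[EXP3]
}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one synthetic study."""

    seed: int = 0
    n_runs: int = 20
    n_voxels: int = 100
    n_sessions: int = 4
    regions: tuple[str, ...] = ("V4like", "TEOlike", "TPlike")
    params: GeneratorParams = field(default_factory=GeneratorParams)
    shrinkage: float | str = "auto"
    alpha: float = 0.05
    #: permutations for every label-permutation test (ROI decoding p-values
    #: and the period x true/false interaction)
    n_perm: int = 199

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"]["truefalse_amplitude"] = list(d["params"]["truefalse_amplitude"])
        d["regions"] = list(d["regions"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return PipelineConfig.from_dict(doc)

    @staticmethod
    def from_dict(doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        if "params" in doc:
            p = dict(doc["params"])
            if "truefalse_amplitude" in p:
                p["truefalse_amplitude"] = tuple(p["truefalse_amplitude"])
            doc["params"] = GeneratorParams(**p)
        if "regions" in doc:
            doc["regions"] = tuple(doc["regions"])
        return PipelineConfig(**doc)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def simulate_region(config: PipelineConfig, region: str) -> tuple[GroundTruth, PatternMatrix]:
    """Plant codes and simulate beta patterns for one region profile."""
    offset = sorted(PROFILES).index(region)
    truth = plant_codes(
        config.n_voxels, PROFILES[region], config.params,
        seed=config.seed * 16 + offset,
    )
    designs = make_design_set(n_runs=config.n_runs, seed=config.seed)
    betas = simulate_betas(designs, truth, n_sessions=config.n_sessions)
    return truth, betas


RED_GREEN_EXEMPLARS = tuple(sum(RED_GREEN_CATEGORIES.values(), []))


def _analysis_registry(pattern: PatternMatrix, config: PipelineConfig) -> dict:
    """Per analysis: (data, statistic, permuted-condition set).

    The statistic maps a PatternMatrix to the scheme's aggregate
    accuracy; the condition set says which labels are exchanged within
    runs to build the permutation null.
    """
    exp1 = pattern.select(experiment=EXP1)
    exp2 = pattern.select(experiment=EXP2)
    exp3 = pattern.select(experiment=EXP3)
    scheme = exemplar_split_folds(RED_GREEN_CATEGORIES)
    scheme_cc = confound_excluded_cases(scheme, DEFAULT_SHAPE_SIMILARITY)
    sh = config.shrinkage
    return {
        "memory_color_2way": (
            exp2,
            lambda p: run_exemplar_split(p, scheme, sh),
            RED_GREEN_EXEMPLARS,
        ),
        "memory_color_2way_confound_excluded": (
            exp2,
            lambda p: run_exemplar_split(p, scheme_cc, sh, restrict_to_kept=True),
            RED_GREEN_EXEMPLARS,
        ),
        "transfer_3way": (
            exp2,
            lambda p: transfer_decode(exp1, p, shrinkage=sh),
            list(CONDITIONS[EXP2]),
        ),
        "truefalse_2way": (
            exp3,
            lambda p: leave_one_run_out(p, list(CONDITIONS[EXP3]), TRUEFALSE_LABELS, sh),
            list(CONDITIONS[EXP3]),
        ),
        "identity_4way": (
            exp3,
            lambda p: leave_one_run_out(p, list(IDENTITY_CONDITIONS), shrinkage=sh),
            list(IDENTITY_CONDITIONS),
        ),
    }


def decode_region(pattern: PatternMatrix, config: PipelineConfig) -> dict:
    """The study's decoding analyses on one region's patterns."""
    return {
        name: runner(data)
        for name, (data, runner, _) in _analysis_registry(pattern, config).items()
    }


def decode_region_with_inference(pattern: PatternMatrix, config: PipelineConfig) -> dict:
    """Decoding results plus one-tailed label-permutation p-values.

    Pooled binomial counts are anti-conservative for ROI schemes whose
    folds reuse test samples, so ROI-level inference permutes condition
    labels within runs instead (the binomial test is reserved for the
    searchlight maps, where counts are used descriptively per sphere).
    """
    out = {}
    for name, (data, runner, perm_conds) in _analysis_registry(pattern, config).items():
        result = runner(data)
        stat = permutation_test(
            lambda p: runner(p).accuracy,
            data,
            lambda rng, p: permute_conditions_within_runs(p, rng, perm_conds),
            n_perm=config.n_perm,
            seed=config.seed,
            tail="one",
        )
        out[name] = (result, stat)
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Simulate, decode and test; return (and optionally write) the report.

    Stage failures raise :class:`StageError` naming the stage; outputs
    written before the failure are retained.
    """
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "regions": {},
    }
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    patterns: dict[str, PatternMatrix] = {}
    for region in config.regions:
        try:
            truth, betas = simulate_region(config, region)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"stage 'simulate' failed for region {region}: {e}") from e
        patterns[region] = betas
        if outdir is not None:
            truth.to_json(outdir / f"{region}_truth.json")
            betas.save(outdir / f"{region}_betas.tsv")

    decoded: dict[str, dict] = {}
    for region, betas in patterns.items():
        try:
            decoded[region] = decode_region_with_inference(betas, config)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"stage 'decode' failed for region {region}: {e}") from e

    try:
        analyses = sorted(next(iter(decoded.values())))
        for region in config.regions:
            report["regions"][region] = {}
            for analysis in analyses:
                res, stat = decoded[region][analysis]
                report["regions"][region][analysis] = {
                    "accuracy": res.accuracy,
                    "chance": res.chance_level,
                    "correct": res.correct,
                    "total": res.total,
                    "p": stat.p,
                    "n_perm": config.n_perm,
                }
        # FDR across regions within each analysis (the ROI-table convention)
        for analysis in analyses:
            ps = [report["regions"][r][analysis]["p"] for r in config.regions]
            for region, q in zip(config.regions, bh_fdr(ps)):
                report["regions"][region][analysis]["q"] = float(q)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'stats' failed: {e}") from e

    # period x true/false interaction in the familiarity-amplitude region
    try:
        if "TPlike" in patterns:
            report["interaction_period_truefalse"] = _interaction_report(
                patterns["TPlike"], config
            )
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'interaction' failed: {e}") from e

    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (outdir / "manifest.json").write_text(
            json.dumps(
                {"config_hash": config.hash(), "seed": config.seed,
                 "config": config.to_dict()},
                indent=2,
            )
        )
    return report


def _interaction_report(pattern: PatternMatrix, config: PipelineConfig) -> dict:
    exp3 = pattern.select(experiment=EXP3)
    rows = exp3.samples.copy()
    rows["roi_mean"] = exp3.values.mean(axis=1)
    rows["tf"] = rows["condition"].map(TRUEFALSE_LABELS)
    res = interaction_period_truefalse(
        rows, n_perm=config.n_perm, seed=config.seed
    )
    first = rows[rows["period"] == "first"]
    d = cohens_d(
        first.loc[first["tf"] == "true", "roi_mean"],
        first.loc[first["tf"] == "false", "roi_mean"],
    )
    return {
        "statistic": res.statistic,
        "p": res.p,
        "tail": res.tail,
        "n_runs": res.n,
        "cohens_d_first_half": d,
        "n_perm": config.n_perm,
        "seed": config.seed,
    }


def null_decoding_calibration(
    n_replicates: int = 200,
    n_runs: int = 20,
    n_voxels: int = 100,
    seed: int = 1,
    shrinkage: float | str = "auto",
) -> pd.DataFrame:
    """Monte-Carlo chance calibration of the three headline decoders.

    Generates ``n_replicates`` fully null datasets (every planted effect
    zero, unit voxel noise) and runs grating-to-object transfer decoding
    (chance 1/3), two-way true/false leave-one-run-out decoding (chance
    1/2) and four-way object-identity decoding (chance 1/4).  Returns one
    row per (replicate, scheme) with accuracy and pooled counts; the mean
    accuracy per scheme should sit at its chance level.

    Per-replicate seeds are spawned from ``seed`` so replicates are
    independent and the whole run is reproducible.
    """
    designs = make_design_set(n_runs=n_runs, seed=seed)
    rows = []
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n_replicates)):
        rep_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        truth = plant_codes(n_voxels, PROFILES["V4like"], GeneratorParams.null(),
                            seed=rep_seed)
        betas = simulate_betas(designs, truth)
        exp3 = betas.select(experiment=EXP3)
        results = {
            "transfer_3way": transfer_decode(
                betas.select(experiment=EXP1), betas.select(experiment=EXP2),
                shrinkage=shrinkage,
            ),
            "truefalse_2way": leave_one_run_out(
                exp3, list(CONDITIONS[EXP3]), TRUEFALSE_LABELS, shrinkage
            ),
            "identity_4way": leave_one_run_out(
                exp3, list(IDENTITY_CONDITIONS), shrinkage=shrinkage
            ),
        }
        for name, res in results.items():
            rows.append(
                {
                    "replicate": i,
                    "scheme": name,
                    "chance": res.chance_level,
                    "accuracy": res.accuracy,
                    "correct": res.correct,
                    "total": res.total,
                }
            )
    return pd.DataFrame(rows)


def make_fixtures(
    outdir: str | Path,
    seed: int = 0,
    n_runs: int = 6,
    n_voxels: int = 100,
    grid_shape: tuple[int, int, int] = (6, 6, 6),
) -> Path:
    """A small packaged synthetic dataset for tests and demos.

    Beta-level patterns (with ground truth) for the three region
    profiles across all three experiments, plus a two-run NIfTI time
    series + events set that exercises the GLM stage.  Layout: one
    directory per region under ``betas/``, the time series under
    ``nifti/`` and a manifest at the root.
    """
    outdir = Path(outdir)
    (outdir / "betas").mkdir(parents=True, exist_ok=True)
    (outdir / "nifti").mkdir(parents=True, exist_ok=True)

    params = GeneratorParams()
    designs = make_design_set(n_runs=n_runs, seed=seed)
    for i, region in enumerate(sorted(PROFILES)):
        truth = plant_codes(n_voxels, PROFILES[region], params, seed=seed * 16 + i)
        betas = simulate_betas(designs, truth)
        betas.save(outdir / "betas" / f"{region}.tsv")
        truth.to_json(outdir / "betas" / f"{region}_truth.json")

    ts_truth = plant_codes(
        int(np.prod(grid_shape)), PROFILES["V4like"], params, seed=seed * 16 + 7
    )
    ts_truth.to_json(outdir / "nifti" / "truth.json")
    for run in (1, 2):
        design = make_design(EXP1, run, seed)
        vol, events = simulate_timeseries(
            design, ts_truth, grid_shape=grid_shape, noise_sd=0.1,
        )
        mio.write_nifti(vol, outdir / "nifti" / f"exp1_run{run}.nii.gz")
        mio.write_events(events, outdir / "nifti" / f"exp1_run{run}_events.tsv")

    manifest = {
        "seed": seed,
        "n_runs": n_runs,
        "n_voxels": n_voxels,
        "grid_shape": list(grid_shape),
        "regions": sorted(PROFILES),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
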