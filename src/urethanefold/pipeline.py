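"""End-to-end orchestration: sequences -> ensembles -> clusters -> torsions ->
H-bonds -> binding decomposition -> titration fits -> library report.

Configuration is a JSON or YAML file validated against a pydantic schema;
all physical defaults live here, every output is stamped with the config
hash and master seed, and the whole run is bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import io as ufio
from .binding import ensemble_binding, rank_oligomers
from .conformers import (
    cluster_ensemble,
    helix_metrics,
    measure_torsions,
    stereo_sign_statistics,
    top_clusters,
    torsion_mode,
)
from .forcefield import ForceFieldParams, default_params
from .hbonds import hbond_statistics
from .molecules import (
    adduct_mz,
    bpa_structure,
    merge_topologies,
    molecular_formula,
    oligourethane_topology,
    parse_sequence,
)
from .sampler import AnnealingSchedule, ComplexSystem, msa_ensemble
from .titration import library_report, read_titration_csv, stern_volmer_fit

__all__ = [
    "PipelineConfig",
    "PipelineConfigError",
    "PipelineStageError",
    "validate_config",
    "run_pipeline",
]

_FLOAT_FMT = "%.10g"


class PipelineConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid pipeline config:\n" + "\n".join(f"- {e}" for e in errors))


class SequenceConfig(BaseModel):
    id: str
    stereo: str
    composition: str | None = None

    @field_validator("stereo")
    @classmethod
    def _stereo_chars(cls, v: str) -> str:
        for pos, ch in enumerate(v, start=1):
            if ch not in "SR":
                raise ValueError(f"illegal stereo character {ch!r} at position {pos}")
        if not v:
            raise ValueError("empty stereo string")
        return v

    @field_validator("composition")
    @classmethod
    def _comp_chars(cls, v: str | None) -> str | None:
        if v is None:
            return v
        for pos, ch in enumerate(v, start=1):
            if ch not in "PM":
                raise ValueError(f"illegal composition character {ch!r} at position {pos}")
        return v


class SamplerConfig(BaseModel):
    n_repeats: int = Field(5, ge=1)
    T_start: float = 298.0
    T_peak: float = 500.0
    T_end: float = 0.0
    sweeps_heat: int = Field(60, ge=1)
    sweeps_equil: int = Field(40, ge=1)
    sweeps_cool: int = Field(100, ge=1)
    production_sweeps: int = Field(400, ge=1)
    production_T: float = 298.0
    stride: int = Field(20, ge=1)

    def schedule(self) -> AnnealingSchedule:
        return AnnealingSchedule(
            T_start=self.T_start,
            T_peak=self.T_peak,
            T_end=self.T_end,
            sweeps_heat=self.sweeps_heat,
            sweeps_equil=self.sweeps_equil,
            sweeps_cool=self.sweeps_cool,
        )


class PipelineConfig(BaseModel):
    sequences: list[SequenceConfig] = Field(min_length=1)
    master_seed: int = 0
    sampler: SamplerConfig = SamplerConfig()
    clustering_cutoff: float = Field(2.0, gt=0)
    top_k: int = Field(5, ge=1)
    skip_fraction: float = Field(0.1, ge=0.0, lt=1.0)
    hbond_dmax: float = Field(3.5, gt=0)
    hbond_theta_min: float = Field(135.0, ge=0, le=180)
    forcefield_params: str | None = None
    titration_csv: str | None = None
    allow_missing_experiment: bool = True
    output_dir: str = "results/pipeline"

    def load_params(self) -> ForceFieldParams:
        if self.forcefield_params:
            return ForceFieldParams.from_json(self.forcefield_params)
        return default_params()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and schema-check a JSON/YAML config; defaults are filled in.

    All violations are aggregated into one :class:`PipelineConfigError`."""
    path = Path(path)
    if not path.exists():
        raise PipelineConfigError([f"config file not found: {path}"])
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    except Exception as exc:  # noqa: BLE001
        raise PipelineConfigError([f"cannot parse {path.name}: {exc}"]) from exc
    if not isinstance(raw, dict) or not raw:
        raise PipelineConfigError(["config must be a non-empty mapping"])
    try:
        cfg = PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise PipelineConfigError(msgs) from exc
    if cfg.titration_csv and not Path(cfg.titration_csv).exists():
        if not cfg.allow_missing_experiment:
            raise PipelineConfigError([f"titration CSV not found: {cfg.titration_csv}"])
    return cfg


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, sequence: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sequence {sequence!r}: {cause}")
        self.stage = stage
        self.sequence = sequence


def _sequence_seed(master_seed: int, index: int) -> int:
    """Documented per-sequence seed rule: counter-based SeedSequence state."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % 2**31)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Run every stage for every configured sequence; returns the report
    bundle (and writes it under the configured output directory)."""
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.load_params()
    stamp = {"config_hash": config.config_hash(), "master_seed": config.master_seed}

    curves = {}
    if config.titration_csv:
        p = Path(config.titration_csv)
        if p.exists():
            curves = read_titration_csv(p)
        elif not config.allow_missing_experiment:
            raise FileNotFoundError(f"titration CSV not found: {p}")

    bpa = bpa_structure()
    report: dict = {"stamp": stamp, "sequences": {}}
    binding_summaries: dict[str, dict] = {}
    fits: dict[str, object] = {}

    for idx, seq_cfg in enumerate(config.sequences):
        seq_id = seq_cfg.id
        seq_dir = outdir / seq_id
        seq_dir.mkdir(parents=True, exist_ok=True)
        entry: dict = {"stereo": seq_cfg.stereo}

        def stage(name, fn, _seq=seq_id):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError(name, _seq, exc) from exc

        residues = stage(
            "build", lambda: parse_sequence(seq_cfg.stereo, seq_cfg.composition)
        )
        topo = stage("build", lambda: oligourethane_topology(residues, name=seq_id))
        formula = molecular_formula(topo)
        entry["formula"] = formula.hill_formula()
        entry["adducts"] = {
            ad: adduct_mz(formula, ad) for ad in ("[M+H]+", "[M+Na]+", "[M-Boc+H]+")
        }

        complex_topo = merge_topologies(topo, bpa.topology)
        system = ComplexSystem(complex_topo, params, ligand_template=bpa.coords)
        seq_seed = _sequence_seed(config.master_seed, idx)
        ens = stage(
            "sample",
            lambda: msa_ensemble(
                system,
                n_repeats=config.sampler.n_repeats,
                schedule=config.sampler.schedule(),
                production_sweeps=config.sampler.production_sweeps,
                production_T=config.sampler.production_T,
                stride=config.sampler.stride,
                master_seed=seq_seed,
            ),
        )
        frames = ens.frames(config.skip_fraction)
        repeats = ens.frame_repeats(config.skip_fraction)
        ufio.write_xyz(frames, seq_dir / "ensemble.xyz")
        energies = pd.DataFrame(
            {
                "frame": np.arange(len(frames)),
                "repeat": repeats,
                "E_total": np.concatenate(
                    [
                        t.energies[int(np.floor(config.skip_fraction * len(t.frames))):]
                        for t in ens.trajectories
                    ]
                ),
            }
        )
        energies.to_csv(seq_dir / "energies.csv", index=False, float_format=_FLOAT_FMT)

        assignment = stage(
            "cluster",
            lambda: cluster_ensemble(frames, cutoff=config.clustering_cutoff),
        )
        tops, coverage = top_clusters(assignment, config.top_k)
        pd.DataFrame(
            {"frame": np.arange(len(frames)), "cluster": assignment.labels}
        ).to_csv(seq_dir / "clusters.csv", index=False)
        entry["clusters"] = {
            "n_clusters": assignment.n_clusters,
            "top": tops,
            "coverage": coverage,
        }

        def torsion_tables():
            rows = []
            tsets = [measure_torsions(f) for f in frames]
            for c in range(assignment.n_clusters):
                members = assignment.members(c)
                for res in range(len(topo.residues)):
                    for torsion in ("phi", "xi", "chi"):
                        vals = np.array(
                            [getattr(tsets[m], torsion)[res] for m in members]
                        )
                        rows.append(
                            {
                                "cluster": c,
                                "residue": res,
                                "torsion": torsion,
                                "mode_deg": torsion_mode(vals),
                                "n": len(members),
                            }
                        )
            return pd.DataFrame(rows), tsets

        torsion_df, _tsets = stage("torsions", torsion_tables)
        torsion_df.to_csv(seq_dir / "torsion_modes.csv", index=False, float_format=_FLOAT_FMT)
        sign_stats = stereo_sign_statistics(frames)
        entry["stereo_sign_fraction"] = {
            "per_residue": [float(x) for x in sign_stats["per_residue"]],
            "mean": sign_stats["mean"],
        }
        entry["helix_medoids"] = {
            str(t["label"]): vars(helix_metrics(frames[t["medoid"]]))
            for t in tops
        }

        hb = stage(
            "hbonds",
            lambda: hbond_statistics(
                frames, assignment, config.hbond_dmax, config.hbond_theta_min
            ),
        )
        pd.DataFrame(
            {
                "frame": np.arange(len(frames)),
                "intra": hb.per_frame_intra,
                "inter": hb.per_frame_inter,
            }
        ).to_csv(seq_dir / "hbonds.csv", index=False, float_format=_FLOAT_FMT)
        entry["hbonds"] = {"mean_intra": hb.mean_intra, "mean_inter": hb.mean_inter}

        summary = stage("bind", lambda: ensemble_binding(frames, params, assignment))
        summary["per_frame"].to_csv(
            seq_dir / "binding.csv", index=False, float_format=_FLOAT_FMT
        )
        binding_summaries[seq_id] = summary
        entry["binding"] = {
            "mean": summary["mean"],
            "sd": summary["sd"],
            "p5": summary["p5"],
            "p95": summary["p95"],
        }

        if seq_id in curves:
            fit = stage("titrate", lambda: stern_volmer_fit(curves[seq_id]))
            fits[seq_id] = fit
            entry["titration"] = {"Kd_molar": fit.Kd, "Ka_per_molar": fit.Ka, "r2": fit.r_squared}
        else:
            fits[seq_id] = None

        report["sequences"][seq_id] = entry

    table, lib_summary = library_report(fits, binding_summaries)
    table.to_csv(outdir / "report.csv", index=False, float_format=_FLOAT_FMT)
    report["library"] = lib_summary
    if len(binding_summaries) >= 2:
        report["library"]["ranking_by_dG"] = rank_oligomers(
            {s: b["mean"]["dG_bind"] for s, b in binding_summaries.items()}
        )
    _json_dump(_to_jsonable(report), outdir / "summary.json")
    (outdir / "summary.md").write_text(_markdown_summary(report))
    return report


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _markdown_summary(report: dict) -> str:
    lines = ["# Oligourethane-BPA pipeline summary", ""]
    lines.append(f"Config hash: `{report['stamp']['config_hash']}`; "
                 f"master seed: {report['stamp']['master_seed']}")
    lines.append("")
    for seq, e in report["sequences"].items():
        lines.append(f"## {seq} ({e['stereo']})")
        lines.append(f"- formula {e['formula']}; adducts: " + ", ".join(
            f"{k} {v:.2f}" for k, v in e["adducts"].items()))
        c = e["clusters"]
        lines.append(
            f"- {c['n_clusters']} clusters; top-{len(c['top'])} coverage {c['coverage']:.2f}"
        )
        lines.append(
            f"- H-bonds per frame: intra {e['hbonds']['mean_intra']:.2f}, "
            f"inter {e['hbonds']['mean_inter']:.2f}"
        )
        b = e["binding"]["mean"]
        lines.append(f"- mean dG_bind {b['dG_bind']:.2f} kcal/mol "
                     f"(vdW {b['dE_vdW']:.2f}, el {b['dE_el']:.2f}, solv {b['dG_solv']:.2f})")
        if "titration" in e:
            lines.append(f"- Stern-Volmer Kd {e['titration']['Kd_molar']*1e3:.2f} mM "
                         f"(R2 {e['titration']['r2']:.3f})")
        lines.append("")
    lib = report.get("library", {})
    if "concordance" in lib:
        lines.append(f"Library trend concordance: {lib['concordance']:.2f}")
    if "ranking_by_dG" in lib:
        lines.append("Ranking by mean dG_bind: " + " > ".join(lib["ranking_by_dG"]))
    lines.append("")
    return "\n".join(lines)
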