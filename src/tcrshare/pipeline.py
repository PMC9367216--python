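"""Stage orchestration: configuration, manifests, and the analysis stages.

Each stage reads its inputs (from the config paths or from upstream stage
outputs), writes tab-separated results plus a JSON run manifest (inputs,
parameters, seed, package version, output row counts) into the output
directory, and is byte-identical when rerun with the same inputs and
seed.  The dependency graph is explicit: a stage that needs an upstream
output raises a :class:`UserError` naming the stage to run first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import annotation as ann
from . import clustering as clu
from . import expansion as exp
from . import gene_usage as gu
from . import io as rio
from . import sharing as sh
from . import simulate as sim
from . import stats as st

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "qc", "tiers", "share", "usage", "cluster",
    "annotate", "diversity", "compare", "report",
)

_FLOAT_FMT = "%.10g"


class UserError(Exception):
    """Configuration or input problem the user can fix."""


@dataclasses.dataclass
class PipelineConfig:
    cohort_dir: Path
    metadata: Path
    out_dir: Path
    antigen_db: Path | None = None
    exclusion_list: Path | None = None
    hla: Path | None = None
    seed: int = 0
    dialect: str = "airr"
    tier_thresholds: tuple[float, float, float] = exp.DEFAULT_THRESHOLDS
    cluster_params: clu.ClusterParams = dataclasses.field(default_factory=clu.ClusterParams)
    sim: sim.SimConfig = dataclasses.field(default_factory=sim.SimConfig)
    track_top_n: int = 4

    def __post_init__(self) -> None:
        h, l, m = self.tier_thresholds
        if not h > l > m > 0:
            raise UserError("tier thresholds must be strictly decreasing and positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise UserError(f"cannot read config {path}: {exc}") from exc
        base = path.parent
        paths = raw.get("paths", {})

        def _p(key: str, required: bool = False) -> Path | None:
            val = paths.get(key)
            if val is None:
                if required:
                    raise UserError(f"config is missing paths.{key}")
                return None
            return (base / val).resolve()

        tiers = raw.get("tiers", {})
        thresholds = (
            float(tiers.get("hyper", 0.01)),
            float(tiers.get("large", 0.001)),
            float(tiers.get("medium", 0.0001)),
        )
        cl = raw.get("cluster", {})
        cluster_params = clu.ClusterParams(
            matrix_name=cl.get("matrix", "BLOSUM62"),
            score_threshold=float(cl.get("score_threshold", 2.5)),
            flank_left=int(cl.get("flank_left", 2)),
            flank_right=int(cl.get("flank_right", 2)),
            require_same_v=bool(cl.get("require_same_v", False)),
        )
        sim_kwargs = raw.get("sim", {})
        seed = int(raw.get("seed", 0))
        try:
            sim_cfg = sim.SimConfig(**sim_kwargs)
        except TypeError as exc:
            raise UserError(f"invalid sim config: {exc}") from exc
        sim_cfg.seed = int(sim_kwargs.get("seed", seed))
        try:
            return cls(
                cohort_dir=_p("cohort_dir", required=True),
                metadata=_p("metadata", required=True),
                out_dir=_p("out_dir", required=True),
                antigen_db=_p("antigen_db"),
                exclusion_list=_p("exclusion_list"),
                hla=_p("hla"),
                seed=seed,
                dialect=str(raw.get("dialect", "airr")),
                tier_thresholds=thresholds,
                cluster_params=cluster_params,
                sim=sim_cfg,
                track_top_n=int(raw.get("track_top_n", 4)),
            )
        except UserError:
            raise


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> int:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
    return len(df)


def _manifest(
    cfg: PipelineConfig, stage: str, inputs: dict, params: dict, outputs: dict[str, int]
) -> None:
    payload = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": params,
        "outputs": outputs,
    }
    path = cfg.out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _load_cohort(cfg: PipelineConfig):
    if not cfg.metadata.exists():
        raise UserError(
            f"metadata not found at {cfg.metadata}; run the 'simulate' stage first "
            "or point paths.metadata at an existing cohort"
        )
    meta = rio.read_metadata(cfg.metadata)
    reps = rio.read_cohort(cfg.cohort_dir, meta, cfg.dialect)
    return reps, meta


def _require(cfg: PipelineConfig, filename: str, producer: str) -> Path:
    path = cfg.out_dir / filename
    if not path.exists():
        raise UserError(f"missing {filename}; run the '{producer}' stage first")
    return path


def stage_simulate(cfg: PipelineConfig) -> None:
    cfg.sim.seed = cfg.seed if cfg.sim.seed == 0 else cfg.sim.seed
    reps, meta, gt = sim.simulate_cohort(cfg.sim)
    sim.write_cohort(cfg.cohort_dir, reps, meta, gt)
    _manifest(
        cfg, "simulate", {"cohort_dir": cfg.cohort_dir},
        {"n_control": cfg.sim.n_control, "n_tumor": cfg.sim.n_tumor,
         "clones_per_sample": cfg.sim.clones_per_sample, "sim_seed": cfg.sim.seed},
        {f"{m.sample_id}.tsv": reps[i].n_unique for i, m in enumerate(meta)} | {
            "metadata.tsv": len(meta), "ground_truth.json": 1},
    )


def stage_qc(cfg: PipelineConfig) -> None:
    reps, meta = _load_cohort(cfg)
    groups = {m.sample_id: m.group for m in meta}
    df = pd.DataFrame(
        [
            (r.sample_id, groups[r.sample_id], r.n_unique, r.total_count)
            for r in reps
        ],
        columns=["sample_id", "group", "n_unique", "total_count"],
    )
    n = _write_tsv(df, cfg.out_dir / "qc.tsv")
    _manifest(cfg, "qc", {"cohort_dir": cfg.cohort_dir, "metadata": cfg.metadata},
              {"dialect": cfg.dialect}, {"qc.tsv": n})


def stage_tiers(cfg: PipelineConfig) -> None:
    reps, _ = _load_cohort(cfg)
    table = exp.tier_abundance_table(reps, cfg.tier_thresholds)
    n = _write_tsv(table, cfg.out_dir / "tiers.tsv")
    _manifest(cfg, "tiers", {"cohort_dir": cfg.cohort_dir},
              {"thresholds": list(cfg.tier_thresholds)}, {"tiers.tsv": n})


def stage_share(cfg: PipelineConfig) -> None:
    reps, meta = _load_cohort(cfg)
    occ = sh.build_occupancy(reps, meta)
    n_occ = _write_tsv(occ, cfg.out_dir / "occupancy.tsv", index=True)

    parts = []
    for rep in reps:
        ct = sh.class_abundance(rep, occ, cfg.tier_thresholds)
        long = ct.stack().rename("abundance").reset_index()
        long.columns = ["sharing_class", "tier", "abundance"]
        long.insert(0, "sample_id", rep.sample_id)
        parts.append(long)
    ct_table = pd.concat(parts, ignore_index=True)
    n_ct = _write_tsv(ct_table, cfg.out_dir / "class_tier_abundance.tsv")

    exclusion = rio.read_exclusion_list(cfg.exclusion_list) if cfg.exclusion_list else set()
    ts = sh.find_tumor_specific_hyper(occ, exclusion, cfg.tier_thresholds[0])
    ts_table = pd.DataFrame(
        sorted((c, c in ts.excluded) for c in ts.candidates),
        columns=["cdr3_aa", "excluded"],
    )
    n_ts = _write_tsv(ts_table, cfg.out_dir / "tumor_specific.tsv")

    outputs = {"occupancy.tsv": n_occ, "class_tier_abundance.tsv": n_ct,
               "tumor_specific.tsv": n_ts}
    if ts.retained:
        top = (
            occ.loc[sorted(ts.retained)]
            .sort_values(["max_fraction_tumor"], ascending=False)
            .head(cfg.track_top_n)
            .index.tolist()
        )
        track = sh.track_clonotypes(reps, top, drop_empty=True)
        track.index.name = "sample_id"
        outputs["tracking.tsv"] = _write_tsv(track, cfg.out_dir / "tracking.tsv", index=True)
    _manifest(cfg, "share", {"cohort_dir": cfg.cohort_dir,
                             "exclusion_list": cfg.exclusion_list or ""},
              {"hyper_threshold": cfg.tier_thresholds[0],
               "track_top_n": cfg.track_top_n}, outputs)


def stage_usage(cfg: PipelineConfig) -> None:
    reps, meta = _load_cohort(cfg)
    outputs = {}
    for axis in ("V", "J"):
        mat = gu.usage_matrix(reps, axis=axis)
        long = mat.stack().rename("weight").reset_index()
        long.columns = ["sample_id", "gene", "weight"]
        outputs[f"usage_{axis}.tsv"] = _write_tsv(long, cfg.out_dir / f"usage_{axis}.tsv")
        comp = gu.compare_usage(mat, meta, design="tumor_vs_control")
        outputs[f"usage_compare_{axis}.tsv"] = _write_tsv(
            comp, cfg.out_dir / f"usage_compare_{axis}.tsv"
        )
    _manifest(cfg, "usage", {"cohort_dir": cfg.cohort_dir},
              {"weighting": "by_count", "design": "tumor_vs_control"}, outputs)


def stage_cluster(cfg: PipelineConfig) -> None:
    reps, _ = _load_cohort(cfg)
    universe = sorted({aa for r in reps for aa in r.df["cdr3_aa"]})
    clusters = clu.build_clusters(universe, cfg.cluster_params)
    table = clu.cluster_table(clusters)
    n = _write_tsv(table[["cluster_id", "cdr3_aa"]], cfg.out_dir / "clusters.tsv")
    prof_rows = []
    for c in clusters:
        prof = clu.position_profile(c.members)
        for pos in range(prof.length):
            prof_rows.append((c.cluster_id, pos, float(prof.entropy[pos])))
    profs = pd.DataFrame(prof_rows, columns=["cluster_id", "position", "entropy"])
    n_p = _write_tsv(profs, cfg.out_dir / "cluster_entropy.tsv")
    _manifest(cfg, "cluster", {"cohort_dir": cfg.cohort_dir},
              dataclasses.asdict(cfg.cluster_params),
              {"clusters.tsv": n, "cluster_entropy.tsv": n_p})


def stage_annotate(cfg: PipelineConfig) -> None:
    if cfg.antigen_db is None:
        raise UserError("paths.antigen_db is required for the annotate stage")
    reps, _ = _load_cohort(cfg)
    cluster_path = _require(cfg, "clusters.tsv", "cluster")
    ctable = pd.read_csv(cluster_path, sep="\t")
    clusters = [
        clu.CDR3Cluster(int(cid), tuple(sorted(sub["cdr3_aa"])))
        for cid, sub in ctable.groupby("cluster_id")
    ]
    db = rio.read_antigen_db(cfg.antigen_db)
    universe = sorted({aa for r in reps for aa in r.df["cdr3_aa"]})
    annotations = ann.annotate(universe, db)
    labeled = ann.label_ebv_clusters(clusters, annotations)
    ann_table = pd.DataFrame(
        [
            (a.cdr3_aa, len(a.matched_records), a.is_ebv,
             ";".join(sorted({r.antigen_species for r in a.matched_records})))
            for a in annotations.values()
            if a.matched_records
        ],
        columns=["cdr3_aa", "n_hits", "is_ebv", "species"],
    ).sort_values("cdr3_aa")
    n_a = _write_tsv(ann_table, cfg.out_dir / "annotations.tsv")
    n_l = _write_tsv(clu.cluster_table(labeled), cfg.out_dir / "clusters_labeled.tsv")
    members = ann.ebv_cluster_members(labeled, annotations)
    rows = [dataclasses.asdict(ann.ebv_abundance(r, members)) for r in reps]
    n_e = _write_tsv(pd.DataFrame(rows), cfg.out_dir / "ebv_abundance.tsv")
    _manifest(cfg, "annotate", {"antigen_db": cfg.antigen_db, "clusters": cluster_path},
              {"n_db_records": len(db), "n_ebv_cluster_cdr3": len(members)},
              {"annotations.tsv": n_a, "clusters_labeled.tsv": n_l,
               "ebv_abundance.tsv": n_e})


def stage_diversity(cfg: PipelineConfig) -> None:
    reps, _ = _load_cohort(cfg)
    n = _write_tsv(st.diversity_table(reps), cfg.out_dir / "diversity.tsv")
    _manifest(cfg, "diversity", {"cohort_dir": cfg.cohort_dir}, {}, {"diversity.tsv": n})


def stage_compare(cfg: PipelineConfig) -> None:
    _, meta = _load_cohort(cfg)
    ebv_path = _require(cfg, "ebv_abundance.tsv", "annotate")
    values = pd.read_csv(ebv_path, sep="\t").set_index("sample_id")["abundance"]
    parts = []
    for design in ("stage_vs_control", "age_binary_60", "sex", "tumor_vs_control"):
        try:
            parts.append(ann.compare_abundance(values, meta, design))
        except ValueError as exc:
            logger.info("design %s skipped: %s", design, exc)
    table = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    n = _write_tsv(table, cfg.out_dir / "comparisons.tsv")
    _manifest(cfg, "compare", {"ebv_abundance": ebv_path}, {}, {"comparisons.tsv": n})


def stage_report(cfg: PipelineConfig) -> None:
    manifests = sorted(cfg.out_dir.glob("manifest_*.json"))
    if not manifests:
        raise UserError("no stage manifests found; run some stages first")
    lines = ["tcrshare cohort report", "======================", ""]
    for mf in manifests:
        if mf.name == "manifest_report.json":
            continue
        payload = json.loads(mf.read_text())
        lines.append(f"stage: {payload['stage']} (seed {payload['seed']})")
        for fname, rows in sorted(payload["outputs"].items()):
            lines.append(f"  {fname}: {rows} rows")
        lines.append("")
    (cfg.out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    _manifest(cfg, "report", {"out_dir": cfg.out_dir}, {},
              {"report.txt": len(lines)})


_STAGE_FNS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "tiers": stage_tiers,
    "share": stage_share,
    "usage": stage_usage,
    "cluster": stage_cluster,
    "annotate": stage_annotate,
    "diversity": stage_diversity,
    "compare": stage_compare,
    "report": stage_report,
}


def run_subcommand(name: str, cfg: PipelineConfig) -> None:
    """Run one pipeline stage by name (see :data:`STAGES`)."""
    if name not in _STAGE_FNS:
        raise UserError(f"unknown stage {name!r}; expected one of {STAGES}")
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    _STAGE_FNS[name](cfg)
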