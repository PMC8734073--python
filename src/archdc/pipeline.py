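"""End-to-end orchestration: simulate → curate → matrices → infer →
slow-fast → support grid → root transfer, from a single YAML config.

Every stage is a pure function of (inputs, config, master seed); re-running
with the same config reproduces all artifacts byte-identically.  Artifacts
are written under the run directory with a checksum manifest; a stage
failure halts the run naming the stage, keeping partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import curation, io_phylo, seqsim, siterates, supermatrix, supportmap, treeinfer
from .substmodel import lg_model

STAGES = ("simulate", "curate", "matrix", "infer", "slowfast", "grid", "root")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {type(cause).__name__}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 7
    sim: dict = field(default_factory=dict)
    curation: dict = field(default_factory=lambda: {"tolerance": 0, "min_per_order": 3})
    trim: dict = field(default_factory=lambda: {
        "max_gap_fraction": supermatrix.DEFAULT_MAX_GAP_FRACTION,
        "max_entropy": supermatrix.DEFAULT_MAX_ENTROPY,
    })
    infer: dict = field(default_factory=lambda: {"bootstrap_replicates": 100})
    slowfast: dict = field(default_factory=lambda: {
        "fractions": list(siterates.DEFAULT_FRACTIONS),
        "group_cap": siterates.DEFAULT_GROUP_CAP,
        "bootstrap_replicates": 25,
    })
    thresholds: dict = field(default_factory=lambda: {"pp": 0.95, "bv": 0.95})
    recoding: list = field(default_factory=lambda: ["dayhoff4", "dayhoff6"])
    burnin_trees: int = 1500  # discarded head of external tree samples
    drop_sequences: dict = field(default_factory=dict)  # family_id -> [taxon ids]

    def __post_init__(self):
        for key, th in self.thresholds.items():
            if not 0 < th <= 1:
                raise ValueError(f"threshold {key}={th} outside (0, 1]")
        gf = self.trim.get("max_gap_fraction", 0.4)
        if not 0 <= gf <= 1:
            raise ValueError(f"max_gap_fraction {gf} outside [0, 1]")
        fr = self.slowfast.get("fractions", [])
        if any(b >= a for a, b in zip(fr, fr[1:])):
            raise ValueError("slow-fast fractions must be strictly decreasing")
        if any(not 0 < f <= 1 for f in fr):
            raise ValueError("slow-fast fractions must lie in (0, 1]")
        if self.infer.get("bootstrap_replicates", 1) < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if self.burnin_trees < 0:
            raise ValueError("burnin_trees must be >= 0")
        for scheme in self.recoding:
            if scheme not in supermatrix.SCHEMES:
                raise ValueError(f"unknown recoding scheme {scheme!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines = []

    def note(self, stage: str, message: str, t0: float | None = None):
        wall = f" [{time.perf_counter() - t0:.2f}s]" if t0 is not None else ""
        self.lines.append(f"{stage}: {message}{wall}")
        self.path.write_text("\n".join(self.lines) + "\n")


def _archaeal_groups(metadata, taxa, cap: int, min_size: int = 2) -> dict:
    """Order-level groups over the curated archaeal taxa, capped per group."""
    arch = metadata[metadata["domain"] == "Archaea"]
    groups = {}
    for order, block in arch.groupby("order"):
        members = sorted(set(block["taxon_id"]) & set(taxa))[:cap]
        if len(members) >= min_size:
            groups[order] = set(members)
    return groups


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "log.txt")
    config.to_yaml(outdir / "config.yaml")
    model = lg_model()
    trim_kw = dict(max_gap_fraction=_trim_param(config.trim, "max_gap_fraction"),
                   max_entropy=_trim_param(config.trim, "max_entropy"))

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        sim_kw = dict(config.sim)
        fam_kw = sim_kw.pop("families", {})
        if isinstance(fam_kw, dict):
            families = seqsim.default_family_specs(**fam_kw)
        else:
            families = [seqsim.FamilySpec(**f) for f in fam_kw]
        dspec = seqsim.DatasetSpec(seed=config.seed, families=families, **sim_kw)
        dataset = seqsim.simulate_dataset(dspec, model=model)
        seqsim.write_dataset(dataset, outdir / "data")
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    log.note("simulate", f"{len(dataset.families)} families, "
             f"{len(dataset.taxon_metadata)} taxa", t0)

    # --- curate -----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        md = dataset.taxon_metadata
        universe = set(md["taxon_id"])
        groups_all = _archaeal_groups(md, universe, cap=10**9)
        assessments = []
        for fam in dataset.families:
            fam.presence_class = curation.classify_family_presence(fam, md)
            drop = set(config.drop_sequences.get(fam.family_id, ()))
            screened = fam.restrict(set(fam.ids) - drop) if drop else fam
            gene_tree = treeinfer.nj_tree(screened, model)
            assessments.append(
                curation.assess_family(screened, gene_tree, groups_all,
                                       universe=universe)
            )
        retained_ids, report = curation.flag_complex_families(
            assessments, tolerance=config.curation.get("tolerance", 0))
        report.to_csv(outdir / "curation_report.tsv", sep="\t", index=False)
        retained = [f for f in dataset.families if f.family_id in set(retained_ids)]
        if not retained:
            raise curation.CurationError("every family was flagged")
        taxa = curation.subsample_taxa(
            md, retained, min_per_order=config.curation.get("min_per_order", 3))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("curate", exc) from exc
    log.note("curate", f"retained {len(retained)}/{len(dataset.families)} families, "
             f"{len(taxa)} taxa", t0)

    # --- matrices ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        matrices = {}
        for subset in ("A", "AE", "AB"):
            m = supermatrix.build_subset(retained, md, subset, taxa=taxa, **trim_kw)
            m.write(outdir / f"matrix_{subset}.fasta",
                    outdir / f"matrix_{subset}.partitions")
            matrices[subset] = m
        recoded = {}
        for scheme in config.recoding:
            r = supermatrix.recode(matrices["AE"], scheme)
            r.write(outdir / f"matrix_AE_{scheme}.fasta")
            recoded[scheme] = r
        supermatrix.stats_table(
            list(matrices.values()) + list(recoded.values())
        ).to_csv(outdir / "matrix_stats.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("matrix", exc) from exc
    log.note("matrix", ", ".join(f"{k}:{m.n_taxa}x{m.length}"
                                 for k, m in matrices.items()), t0)

    # --- infer ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        n_boot = config.infer.get("bootstrap_replicates", 100)
        trees = {}
        for i, (subset, m) in enumerate(sorted(matrices.items())):
            trees[subset] = treeinfer.bootstrap_support(
                m, model, n_replicates=n_boot, seed=config.seed + 100 + i)
            io_phylo.write_newick(trees[subset], outdir / f"tree_{subset}.nwk")
        bacteria = sorted(
            set(md.loc[md["domain"] == "Bacteria", "taxon_id"]) & set(matrices["AB"].ids))
        rooted_ab = treeinfer.root_with_outgroup(trees["AB"], bacteria)
        io_phylo.write_newick(rooted_ab, outdir / "tree_AB_rooted.nwk")
    except Exception as exc:
        raise StageError("infer", exc) from exc
    log.note("infer", f"{len(trees)} trees, {n_boot} bootstrap replicates", t0)

    # --- slowfast ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        cap = config.slowfast.get("group_cap", siterates.DEFAULT_GROUP_CAP)
        sf_groups = siterates.GroupSet(
            _archaeal_groups(md, set(matrices["A"].ids), cap), cap=cap)
        sf_boot = config.slowfast.get("bootstrap_replicates", 25)

        def infer_cb(m):
            return treeinfer.bootstrap_support(m, model, n_replicates=sf_boot,
                                               seed=config.seed + 500)

        steps = siterates.run_series(
            matrices["A"], sf_groups, infer_cb,
            fractions=config.slowfast.get("fractions", siterates.DEFAULT_FRACTIONS),
            reference_tree=trees["A"],
            pp_threshold=config.thresholds.get("bv", 0.95), support_kind="bv")
        profile = siterates.site_rate(matrices["A"], sf_groups)
        profile.to_frame().to_csv(outdir / "siterate_profile.tsv", sep="\t",
                                  index=False)
        siterates.series_trace(steps).to_csv(outdir / "slowfast_trace.tsv",
                                             sep="\t", index=False)
        for step in steps:
            if step.tree is not None:
                io_phylo.write_newick(step.tree,
                                      outdir / f"tree_A_{step.label}.nwk")
    except Exception as exc:
        raise StageError("slowfast", exc) from exc
    log.note("slowfast", f"{len(steps)} steps", t0)

    # --- grid -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        analyses = [(s, trees[s], "bv") for s in ("A", "AE", "AB")]
        table = supportmap.support_grid(trees["A"], analyses)
        table.to_tsv(outdir / "support_grid.tsv")
    except Exception as exc:
        raise StageError("grid", exc) from exc
    log.note("grid", f"{len(table.branch_ids)} branches x {len(analyses)} analyses", t0)

    # --- root transfer ----------------------------------------------------
    t0 = time.perf_counter()
    try:
        arch = sorted(set(md.loc[md["domain"] == "Archaea", "taxon_id"])
                      & set(matrices["AB"].ids))
        arch_rooted = rooted_ab.extract_tree_with_taxa_labels(arch)
        arch_rooted.is_rooted = True
        rooted_a = supportmap.transfer_root(trees["A"], arch_rooted)
        io_phylo.write_newick(rooted_a, outdir / "tree_A_rooted.nwk")
        root_status = "transferred"
    except Exception as exc:
        raise StageError("root", exc) from exc
    log.note("root", root_status, t0)

    # --- manifest ---------------------------------------------------------
    files = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_dir() or path.name in ("manifest.json", "log.txt"):
            continue
        files[str(path.relative_to(outdir))] = _sha256(path)
    manifest = {"seed": config.seed, "files": files}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _trim_param(d: dict, key: str):
    defaults = {
        "max_gap_fraction": supermatrix.DEFAULT_MAX_GAP_FRACTION,
        "max_entropy": supermatrix.DEFAULT_MAX_ENTROPY,
    }
    return d.get(key, defaults[key])
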