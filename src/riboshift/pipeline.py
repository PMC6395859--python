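"""End-to-end orchestration of the analysis stages with config and manifest.

Stage order: ingest -> psite -> coverage -> {diffexpr, polarity, metagene,
stalling}. Each stage writes its tables under ``output_dir`` and records them
in a run manifest (with SHA-256 checksums and a full parameter echo) so that
identical config + seed gives identical manifests. Stages communicate through
an in-memory state; a downstream stage requested on its own reloads what it
can from disk and otherwise raises a dependency error naming the missing
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage as cov
from . import diffexpr as de
from . import io as rio
from . import positional as pos
from . import stalling as st

logger = logging.getLogger(__name__)

STAGE_ORDER = ["ingest", "psite", "coverage", "diffexpr", "polarity", "metagene", "stalling"]

DEFAULT_PARAMS: dict = {
    "max_multiplicity": 1,
    "max_multiplicity_diffexpr": 2,
    "min_reads_per_length": 5000,
    "f0_threshold": 0.55,
    "rna_floor": 1.0,
    "min_expression": 1.0,
    "pseudocount": 0.5,
    "min_gene_reads": 64,
    "min_site_density": 0.25,
    "polarity_trim": 15,
    "min_gene_density": 1.0,
    "metagene_min_genes": 50,
    "alpha": 0.05,
}


class PipelineError(RuntimeError):
    pass


@dataclass
class LibrarySpec:
    condition: str
    replicate: int
    ribo: str
    rna: str

    @property
    def key(self) -> str:
        return f"{self.condition}_{self.replicate}"


@dataclass
class RunConfig:
    annotation: str
    sequences: str
    libraries: list[LibrarySpec]
    output_dir: str = "riboshift_out"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params = {**DEFAULT_PARAMS, **(self.params or {})}
        conds = {lib.condition for lib in self.libraries}
        if len(conds) != 2:
            raise ValueError(f"exactly two conditions required, got {sorted(conds)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        libs = [LibrarySpec(**d) for d in raw.pop("libraries")]
        return cls(libraries=libs, **raw)

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [self.annotation, self.sequences]
            + [lib.ribo for lib in self.libraries]
            + [lib.rna for lib in self.libraries]
            if not Path(p).exists()
        ]
        if missing:
            raise PipelineError(f"missing input files: {missing}")

    def conditions(self) -> tuple[str, str]:
        """(deficient-like, proficient-like): explicit names win, else sorted order."""
        conds = sorted({lib.condition for lib in self.libraries})
        for marker in ("deficient", "depleted"):
            for c in conds:
                if marker in c.lower():
                    other = [x for x in conds if x != c][0]
                    return c, other
        return conds[0], conds[1]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Stateful runner for one configuration."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}
        self.manifest: dict = {
            "config": {
                "annotation": config.annotation,
                "sequences": config.sequences,
                "libraries": [vars(lib) for lib in config.libraries],
                "seed": config.seed,
                "params": dict(sorted(config.params.items())),
            },
            "inputs": {},
            "stages": {},
        }

    # -- helpers -----------------------------------------------------------

    def _emit(self, stage: str, name: str, writer) -> Path:
        path = self.out / name
        writer(path)
        self.manifest["stages"].setdefault(stage, {})[name] = _sha256(path)
        return path

    def _require(self, key: str, stage: str, needed_by: str):
        if key not in self.state and not self._reload(key):
            raise PipelineError(
                f"stage '{needed_by}' requires outputs of stage '{stage}'; run it first"
            )
        return self.state[key]

    def _reload(self, key: str) -> bool:
        """Best-effort reload of upstream state from a previous run's files."""
        try:
            if key == "annotation":
                p = self.out / "annotation.gff3"
                if p.exists():
                    self.state["annotation"] = rio.read_annotation(p, "GFF3")
                    return True
            if key == "psite":
                ann = self.state.get("annotation")
                if ann is None:
                    return False
                lengths = {tx: int(n) for tx, n in ann["tx_length"].items()}
                tracks = {}
                for lib in self.cfg.libraries:
                    p = self.out / f"psite_{lib.key}.bedgraph"
                    if not p.exists():
                        return False
                    tracks[lib.key] = rio.read_bedgraph(p, lengths)
                sizes = pd.read_csv(self.out / "library_sizes.tsv", sep="\t", index_col=0)
                self.state["psite"] = {
                    k: cov.PsiteCoverage(counts=t, library_size=float(sizes.loc[k, "library_size"]))
                    for k, t in tracks.items()
                }
                return True
        except (OSError, KeyError):
            return False
        return False

    # -- stages ------------------------------------------------------------

    def stage_ingest(self) -> None:
        cfg = self.cfg
        cfg.validate_paths()
        for p in [cfg.annotation, cfg.sequences] + [lib.ribo for lib in cfg.libraries] + [
            lib.rna for lib in cfg.libraries
        ]:
            self.manifest["inputs"][str(p)] = _sha256(Path(p))
        dialect = "BED" if str(cfg.annotation).lower().endswith((".bed",)) else "GFF3"
        ann = rio.read_annotation(cfg.annotation, dialect)
        seqs = rio.read_sequences(cfg.sequences)
        if (ann["tx_length"] <= 0).any():
            ann["tx_length"] = ann.index.map(lambda t: len(seqs[t])).astype(int)
        self.state["annotation"] = ann
        self.state["sequences"] = seqs
        mm1 = int(cfg.params["max_multiplicity"])
        mm2 = int(cfg.params["max_multiplicity_diffexpr"])
        self.state["ribo_reads"] = {
            lib.key: rio.read_alignments(lib.ribo, max_multiplicity=mm1) for lib in cfg.libraries
        }
        self.state["ribo_reads_mm2"] = {
            lib.key: rio.read_alignments(lib.ribo, max_multiplicity=mm2) for lib in cfg.libraries
        }
        self.state["rna_reads"] = {
            lib.key: rio.read_alignments(lib.rna, max_multiplicity=mm2) for lib in cfg.libraries
        }
        self._emit("ingest", "annotation.gff3", lambda p: rio.write_annotation(ann, p, "GFF3"))

    def stage_psite(self) -> None:
        ann = self._require("annotation", "ingest", "psite")
        reads = self._require("ribo_reads", "ingest", "psite")
        P = self.cfg.params
        offsets, psite, rna_cov = {}, {}, {}
        for lib in self.cfg.libraries:
            ot = cov.calibrate_offsets(
                reads[lib.key],
                ann,
                min_reads_per_length=int(P["min_reads_per_length"]),
                f0_threshold=float(P["f0_threshold"]),
            )
            offsets[lib.key] = ot
            psite[lib.key] = cov.assign_psites(reads[lib.key], ot, ann)
            rna_cov[lib.key] = cov.rna_nt_coverage(self.state["rna_reads"][lib.key], ann)
            self._emit(
                "psite",
                f"offsets_{lib.key}.tsv",
                lambda p, ot=ot: rio.write_table(ot.to_frame(), p),
            )
            self._emit(
                "psite",
                f"psite_{lib.key}.bedgraph",
                lambda p, c=psite[lib.key]: rio.write_bedgraph(c.counts, p),
            )
        self.state["offsets"] = offsets
        self.state["psite"] = psite
        self.state["rna_cov"] = rna_cov
        sizes = pd.DataFrame(
            {"library_size": {k: c.library_size for k, c in psite.items()}}
        )
        self._emit("psite", "library_sizes.tsv", lambda p: rio.write_table(sizes, p))

    def stage_coverage(self) -> None:
        ann = self._require("annotation", "ingest", "coverage")
        psite = self._require("psite", "psite", "coverage")
        rna_cov = self._require("rna_cov", "psite", "coverage")
        P = self.cfg.params
        ribo_genes, rna_genes, codon_tables, load_orf, load_pos = {}, {}, {}, {}, {}
        for lib in self.cfg.libraries:
            k = lib.key
            ribo_genes[k] = cov.compute_gene_coverage(psite[k], ann)
            rna_genes[k] = cov.rna_gene_counts(self.state["rna_reads"][k], ann)
            codon_tables[k] = cov.per_codon_coverage(psite[k], ann)
            load_orf[k] = cov.compute_ribosomal_load(ribo_genes[k], rna_genes[k])
            load_pos[k] = cov.position_load(psite[k], rna_cov[k], rna_floor=float(P["rna_floor"]))
            self._emit("coverage", f"genes_ribo_{k}.tsv", lambda p, d=ribo_genes[k]: rio.write_table(d, p))
            self._emit("coverage", f"genes_rna_{k}.tsv", lambda p, d=rna_genes[k]: rio.write_table(d, p))
            self._emit("coverage", f"load_orf_{k}.tsv", lambda p, d=load_orf[k]: rio.write_table(d.to_frame(), p))
        self.state.update(
            ribo_genes=ribo_genes, rna_genes=rna_genes, codon_tables=codon_tables,
            load_orf=load_orf, load_pos=load_pos,
        )

    def stage_diffexpr(self) -> None:
        ann = self._require("annotation", "ingest", "diffexpr")
        self._require("offsets", "psite", "diffexpr")
        P = self.cfg.params
        dcond, pcond = self.cfg.conditions()
        # double-mapped reads retained at this stage (paralog-tolerant mode)
        gene = {}
        for lib in self.cfg.libraries:
            k = lib.key
            ot = self.state["offsets"][k]
            psite_mm2 = cov.assign_psites(self.state["ribo_reads_mm2"][k], ot, ann)
            gene[("ribo", k)] = cov.compute_gene_coverage(psite_mm2, ann)
            gene[("rna", k)] = cov.rna_gene_counts(self.state["rna_reads"][k], ann)
            gene[("load", k)] = cov.compute_ribosomal_load(
                gene[("ribo", k)], gene[("rna", k)]
            ).to_frame("rpkm")
        results = {}
        for metric in ("ribo", "rna", "load"):
            args = [
                gene[(metric, f"{c}_{r}")]["rpkm"]
                for c in (dcond, pcond)
                for r in (1, 2)
            ]
            min_expr = float(P["min_expression"]) if metric != "load" else 0.0
            res = de.differential_gene_sets(
                *args, min_expression=min_expr, pseudocount=float(P["pseudocount"])
            )
            results[metric] = res
            self._emit("diffexpr", f"diffexpr_{metric}.tsv", lambda p, d=res: rio.write_table(d, p))
        summary = pd.DataFrame(
            {m: {"n_up": r.attrs["n_up"], "n_down": r.attrs["n_down"]} for m, r in results.items()}
        )
        self._emit("diffexpr", "diffexpr_summary.tsv", lambda p: rio.write_table(summary, p))
        self.state["diffexpr"] = results

    def _load_tracks(self, key: str) -> dict[str, np.ndarray]:
        """Position-level ribosomal load where defined, else raw P-site density."""
        load_pos = self.state.get("load_pos")
        if load_pos is not None:
            return load_pos[key]
        logger.info("using raw P-site density for %s (no RNA track)", key)
        return self.state["psite"][key].counts

    def stage_polarity(self) -> None:
        ann = self._require("annotation", "ingest", "polarity")
        self._require("load_pos", "coverage", "polarity")
        P = self.cfg.params
        tables = {}
        for lib in self.cfg.libraries:
            t = pos.polarity_table(self._load_tracks(lib.key), ann, trim=int(P["polarity_trim"]))
            tables[lib.key] = t
            self._emit("polarity", f"polarity_{lib.key}.tsv", lambda p, d=t: rio.write_table(d, p))
        dcond, pcond = self.cfg.conditions()
        rows = []
        for r in (1, 2):
            w, pval = pos.compare_polarity_distributions(
                tables[f"{dcond}_{r}"]["polarity"], tables[f"{pcond}_{r}"]["polarity"]
            )
            rows.append({"comparison": f"{dcond}_vs_{pcond}_rep{r}", "W": w, "p": pval})
        summary = pd.DataFrame(rows).set_index("comparison")
        self._emit("polarity", "polarity_tests.tsv", lambda p: rio.write_table(summary, p))
        self.state["polarity"] = tables

    def stage_metagene(self) -> None:
        ann = self._require("annotation", "ingest", "metagene")
        self._require("load_pos", "coverage", "metagene")
        P = self.cfg.params
        profiles = {}
        for lib in self.cfg.libraries:
            for anchor in ("start", "stop"):
                prof = pos.metagene_profile(
                    self._load_tracks(lib.key),
                    ann,
                    anchor=anchor,
                    min_gene_density=float(P["min_gene_density"]),
                    min_genes=int(P["metagene_min_genes"]),
                )
                profiles[(lib.key, anchor)] = prof
                self._emit(
                    "metagene",
                    f"metagene_{anchor}_{lib.key}.tsv",
                    lambda p, d=prof: rio.write_table(d.to_frame(), p),
                )
        self.state["metagene"] = profiles

    def stage_stalling(self) -> None:
        ann = self._require("annotation", "ingest", "stalling")
        codon_tables = self._require("codon_tables", "coverage", "stalling")
        seqs = self._require("sequences", "ingest", "stalling")
        P = self.cfg.params
        dcond, pcond = self.cfg.conditions()
        fds = {}
        for r in (1, 2):
            norm_d = st.codon_density_table(
                codon_tables[f"{dcond}_{r}"], min_gene_reads=float(P["min_gene_reads"])
            )
            norm_p = st.codon_density_table(
                codon_tables[f"{pcond}_{r}"], min_gene_reads=float(P["min_gene_reads"])
            )
            fds[r] = st.fold_difference(
                norm_d, norm_p, min_site_density=float(P["min_site_density"])
            )
        sites = st.select_stall_sites(fds[1], fds[2])
        self._emit("stalling", "stall_sites.tsv", lambda p: rio.write_table(sites, p))
        universe = st.extract_context(sites, ann, seqs)
        background = st.background_frequencies(universe)
        enrich = {}
        for tail in ("high", "low"):
            sel = sites.index[sites["selected"] == tail]
            fg = universe.loc[universe.index.intersection(sel)]
            if len(fg) < 20:
                logger.warning("tail %s: only %d sites with context; logo skipped", tail, len(fg))
                continue
            cells = st.logo_enrichment(fg, background, alpha=float(P["alpha"]))
            enrich[tail] = cells
            self._emit("stalling", f"logo_{tail}.tsv", lambda p, d=cells: rio.write_table(d, p))
        self.state["stalling"] = {"sites": sites, "enrichment": enrich, "background": background}

    # -- driver ------------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> dict:
        todo = STAGE_ORDER if stages is None else [s for s in STAGE_ORDER if s in set(stages)]
        unknown = set(stages or []) - set(STAGE_ORDER)
        if unknown:
            raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
        for stage in todo:
            logger.info("running stage %s", stage)
            getattr(self, f"stage_{stage}")()
        manifest_path = self.out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return self.manifest


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages (all by default) and return the manifest."""
    return Pipeline(config).run(stages)
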