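"""End-to-end orchestration: structure -> repeats -> divergence -> trees.

Every stage writes deterministic TSV/Newick artifacts into a run directory;
TSV files start with a comment header carrying the config hash and seed, and
Newick files carry the same information in a leading bracket comment.  A
manifest records checksums so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import divergence as dv
from . import parsimony as mp
from . import repeats as rp
from . import simulate as sim
from . import structure as st
from ._util import stable_hash
from .io import AnnotatedGenome, read_genbank, write_genbank, write_tsv_report

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # simulate | genbank_dir
    genbank_dir: str | None = None
    sim_scale: float = 1.0
    seed: int = 0
    outdir: str = "run"
    species_labels: dict[str, str] = field(default_factory=dict)
    outgroups: list[str] = field(default_factory=list)
    hotspot_threshold_pct: float = 1.0
    repeat_min_len: int = 30
    repeat_min_identity: float = 0.90
    palindrome_gap_max: int = 3000
    tandem_gap_max: int = 10
    bootstrap_replicates: int = 200
    search_method: str = "tbr_heuristic"

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # where the run lands does not change what it computes
        return stable_hash(json.dumps(d, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key=value text; list values comma-separated, maps as k:v pairs."""
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            if isinstance(cur, bool):
                setattr(cfg, key, val.lower() in ("1", "true", "yes"))
            elif isinstance(cur, int):
                setattr(cfg, key, int(val))
            elif isinstance(cur, float):
                setattr(cfg, key, float(val))
            elif isinstance(cur, list):
                setattr(cfg, key, [v.strip() for v in val.split(",") if v.strip()])
            elif isinstance(cur, dict):
                pairs = [v.split(":") for v in val.split(",") if v.strip()]
                setattr(cfg, key, {k.strip(): v.strip() for k, v in pairs})
            else:
                setattr(cfg, key, val)
        return cfg


def _header(cfg: PipelineConfig) -> str:
    return f"config_hash={cfg.config_hash()} seed={cfg.seed}"


def load_genomes(cfg: PipelineConfig):
    """Returns (genomes, truth-or-None, species_labels, outgroups)."""
    if cfg.mode == "simulate":
        sc = sim.default_config() if cfg.sim_scale >= 1.0 else sim.demo_config(cfg.sim_scale)
        genomes, truth = sim.simulate(sc, seed=cfg.seed)
        return genomes, truth, dict(sc.species_labels), list(sc.outgroups)
    if cfg.mode == "genbank_dir":
        if not cfg.genbank_dir:
            raise StageError("genbank_dir mode needs genbank_dir=<path>")
        genomes = {}
        for p in sorted(Path(cfg.genbank_dir).glob("*.gb")) + sorted(
            Path(cfg.genbank_dir).glob("*.gbk")
        ):
            g = read_genbank(p)
            genomes[g.id] = g
        if not genomes:
            raise StageError(f"no GenBank records in {cfg.genbank_dir}")
        labels = cfg.species_labels or {t: genomes[t].organism or t for t in genomes}
        return genomes, None, labels, list(cfg.outgroups)
    raise StageError(f"unknown mode {cfg.mode!r}")


def run_pipeline(cfg: PipelineConfig) -> dict[str, object]:
    """Run all stages; returns in-memory results keyed by stage."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    stage = "load"
    try:
        genomes, truth, labels, outgroups = load_genomes(cfg)
        results["genomes"] = genomes
        results["truth"] = truth
        taxa = sorted(genomes)
        ingroup = [t for t in taxa if t not in outgroups]

        if cfg.mode == "simulate":
            gdir = out / "genomes"
            gdir.mkdir(exist_ok=True)
            for t in taxa:
                write_genbank(genomes[t], gdir / f"{t}.gb")

        stage = "structure"
        structures = {t: st.detect_quadripartite(genomes[t]) for t in taxa}
        results["structures"] = structures
        rows = []
        for t in taxa:
            s = structures[t]
            for region, (a, b) in (
                ("LSC", s.lsc), ("IRb", s.irb), ("SSC", s.ssc), ("IRa", s.ira)
            ):
                rows.append(
                    {
                        "genome": t, "region": region,
                        "start": a + 1, "end": b,  # 1-based inclusive for reports
                        "length": b - a,
                        "ir_mismatches": s.mismatches_between_ir_copies,
                    }
                )
        write_tsv_report(
            rows, out / "structure.tsv",
            columns=["genome", "region", "start", "end", "length", "ir_mismatches"],
            header_comment=_header(cfg),
        )
        jrows = []
        for t in taxa:
            for rec in st.junction_genes(genomes[t], structures[t]):
                jrows.append({"genome": t, **rec})
        write_tsv_report(
            jrows, out / "junction_genes.tsv",
            columns=["genome", "junction", "gene_name", "bp_inside_ir",
                     "bp_inside_sc", "pseudogene_like"],
            header_comment=_header(cfg),
        )
        crows = []
        for t in taxa:
            c = st.composition_stats(genomes[t])
            inv = st.gene_inventory(genomes[t], structures[t])
            crows.append(
                {
                    "genome": t,
                    "gc_pct": round(c.gc_pct, 2), "at_pct": round(c.at_pct, 2),
                    "protein_pct": round(c.protein_pct, 2),
                    "trna_pct": round(c.trna_pct, 2), "rrna_pct": round(c.rrna_pct, 2),
                    "coding_pct": round(c.coding_pct, 2),
                    "noncoding_pct": round(c.noncoding_pct, 2),
                    "total_functional": inv.total_functional,
                    "unique_genes": inv.unique_genes,
                    "ir_duplicated": inv.ir_duplicated,
                }
            )
        write_tsv_report(
            crows, out / "composition.tsv", sort_by="genome", header_comment=_header(cfg)
        )
        results["composition"] = crows

        stage = "repeats"
        classified: dict[str, list[rp.RepeatHit]] = {}
        for t in taxa:
            s = structures[t]
            hits = rp.find_repeat_pairs(
                genomes[t].sequence,
                min_len=cfg.repeat_min_len,
                min_identity=cfg.repeat_min_identity,
                exclude=[s.irb],
            )
            merged = rp.merge_hits(hits, genomes[t].sequence)
            classified[t] = rp.classify_hits(
                merged, genomes[t], s,
                palindrome_gap_max=cfg.palindrome_gap_max,
                tandem_gap_max=cfg.tandem_gap_max,
            )
        results["repeats"] = classified
        hrows = [
            {
                "genome": t,
                "copy1_start": h.copy1[0] + 1, "copy1_end": h.copy1[1],
                "copy2_start": h.copy2[0] + 1, "copy2_end": h.copy2[1],
                "orientation": h.orientation, "length": h.length,
                "identity": round(h.identity, 4), "category": h.category,
                "context": h.context, "genes": ",".join(h.gene_hits),
            }
            for t in taxa for h in classified[t]
        ]
        write_tsv_report(
            hrows, out / "repeats.tsv",
            columns=["genome", "copy1_start", "copy1_end", "copy2_start", "copy2_end",
                     "orientation", "length", "identity", "category", "context", "genes"],
            header_comment=_header(cfg),
        )
        summary = rp.summarize_repeats(classified)
        with open(out / "repeat_summary.tsv", "w") as fh:
            fh.write(f"# {_header(cfg)}\n")
            summary.to_csv(fh, sep="\t", index=False)

        stage = "hotspots"
        records = dv.scan_hotspots(
            genomes, structures,
            threshold_pct=cfg.hotspot_threshold_pct,
            include_outgroups=False, outgroups=outgroups,
        )
        results["hotspots"] = records
        write_tsv_report(
            [
                {
                    "region": r.name, "class": r.klass,
                    "aligned_length": r.aligned_length,
                    "variable_columns": r.variable_columns,
                    "variable_pct": round(r.variable_pct, 4),
                    "indel_columns": r.indel_columns,
                    "is_hotspot": r.is_hotspot,
                }
                for r in records
            ],
            out / "hotspots.tsv",
            columns=["region", "class", "aligned_length", "variable_columns",
                     "variable_pct", "indel_columns", "is_hotspot"],
            header_comment=_header(cfg),
        )

        stage = "distances"
        wga, _ = dv.build_whole_genome_alignment(genomes, structures, taxa=taxa)
        results["wga"] = wga
        dist = dv.p_distance_summary(wga, labels, outgroups)
        results["distances"] = dist
        with open(out / "p_distances.tsv", "w") as fh:
            fh.write(f"# {_header(cfg)}\n")
            fh.write("taxon\t" + "\t".join(dist.taxa) + "\n")
            for i, t in enumerate(dist.taxa):
                fh.write(t + "\t" + "\t".join(f"{dist.matrix[i, j]:.8f}" for j in range(len(dist.taxa))) + "\n")
            fh.write(f"# mean_all={dist.mean_all:.6g} mean_between={dist.mean_between_species:.6g} "
                     f"mean_within={dist.mean_within_species:.6g}\n")
        tally = dv.tally_variants(wga)
        results["variant_tally"] = tally
        write_tsv_report(
            [
                {"partition": p, **{k: v for k, v in tally[p].items()}}
                for p in ("coding", "intron_spacer", "LSC", "SSC", "IR")
            ],
            out / "variant_tally.tsv",
            columns=["partition", "transition", "transversion", "indel"],
            header_comment=_header(cfg),
        )

        stage = "trees"
        partitions = mp.build_partitions(wga, outgroups=outgroups)
        results["partitions"] = partitions
        prow = []
        results["trees"] = {}
        for name in mp.PARTITION_NAMES:
            matrix = partitions[name]
            boot = mp.bootstrap_support(
                matrix, n_replicates=cfg.bootstrap_replicates,
                method=cfg.search_method, seed=cfg.seed,
            )
            ci, ri, rc = mp.tree_indices(boot, matrix)
            results["trees"][name] = boot
            dt = mp.to_dendropy(boot.best_trees[0], matrix.taxa, boot.supports)
            nwk = dt.as_string(schema="newick", suppress_rooting=True).strip()
            with open(out / f"tree_{name}.nwk", "w") as fh:
                fh.write(f"[&{_header(cfg)}]\n{nwk}\n")
            ing_rows = np.array([matrix.taxa.index(t) for t in ingroup])
            sub = mp.CharacterMatrix(ingroup, matrix.rows[ing_rows], name)
            counts = np.stack([(sub.rows == b).sum(axis=0) for b in range(4)])
            var = int((((counts > 0).sum(axis=0)) >= 2).sum())
            prow.append(
                {
                    "partition": name,
                    "aligned_length": matrix.length,
                    "variable_sites_ingroup": var,
                    "variable_pct_ingroup": round(100.0 * var / matrix.length, 3),
                    "parsimony_informative": boot.n_parsimony_informative,
                    "tree_length": boot.length,
                    "CI": "NA" if boot.CI is None else round(boot.CI, 4),
                    "RI": "NA" if boot.RI is None else round(boot.RI, 4),
                    "RC": "NA" if boot.RC is None else round(boot.RC, 4),
                    "min_bootstrap": round(min(boot.supports.values()), 1)
                    if boot.supports else "NA",
                }
            )
        write_tsv_report(
            prow, out / "partition_stats.tsv",
            columns=["partition", "aligned_length", "variable_sites_ingroup",
                     "variable_pct_ingroup", "parsimony_informative", "tree_length",
                     "CI", "RI", "RC", "min_bootstrap"],
            header_comment=_header(cfg),
        )

        stage = "manifest"
        manifest = {
            "config": dataclasses.asdict(cfg),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "files": {},
        }
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest["files"][str(p.relative_to(out))] = hashlib.sha256(
                    p.read_bytes()
                ).hexdigest()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        results["manifest"] = manifest
        return results
    except Exception as exc:  # pragma: no cover - error path formatting
        raise StageError(f"pipeline failed at stage {stage!r}: {exc}") from exc
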