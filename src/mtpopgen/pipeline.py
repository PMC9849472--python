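"""End-to-end analysis pipeline.

Runs the package's analyses in the standard order — per-population
diversity and neutrality, pairwise Fst / gene flow / MDS, mismatch
distributions with expansion fits, optional haplogroup classification and
admixture partition, optional clade dating and haplotype networks — and
writes a bundle of TSV reports plus a provenance log.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coalsim, dating, diversity, haplogroups, mismatch, network, structure
from .core import (
    PopulationDataset,
    RegionSet,
    STAT_REGIONS,
    collapse_haplotypes,
    load_dataset,
    load_reference,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str
    pops: str
    reference: str
    out_dir: str
    regions: tuple[tuple[int, int], ...] = STAT_REGIONS.regions
    tree_table: str | None = None
    clades: list[str] = field(default_factory=list)  # newick paths
    reps: int = 1000
    bootstraps: int = 100
    permutations: int = 100
    seed: int = 1
    build_network: bool = False

    def validate(self) -> None:
        for label, path in (("fasta", self.fasta), ("pops", self.pops),
                            ("reference", self.reference)):
            if not Path(path).is_file():
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.tree_table and not Path(self.tree_table).is_file():
            raise FileNotFoundError(f"tree table not found: {self.tree_table}")
        for p in self.clades:
            if not Path(p).is_file():
                raise FileNotFoundError(f"clade newick not found: {p}")
        RegionSet(self.regions)  # raises on malformed bounds

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["regions"] = [list(r) for r in self.regions]
        return json.dumps(d, indent=2)


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> Path:
    path = out_dir / name
    df.to_csv(path, sep="\t", float_format="%.6g", na_rep="na")
    return path


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns the mapping of report name -> written path.

    Any stage failure aborts with the stage name in the raised error;
    reports written before the failure are retained.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mtpopgen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict[str, Path] = {"log": log_path}
    stage = "load"
    try:
        logger.info("mtpopgen %s | python %s | numpy %s | seed %d",
                    __version__, sys.version.split()[0], np.__version__, config.seed)
        logger.info("config: %s", config.to_json())
        reference = load_reference(config.reference)
        ds = load_dataset(config.fasta, config.pops, reference,
                          RegionSet(config.regions))
        logger.info("loaded %d samples, %d populations", ds.n, len(ds.populations))

        stage = "diversity"
        div = diversity.diversity_table(ds, reps=config.reps, seed=config.seed)
        outputs["diversity"] = _write(div, out_dir, "diversity.tsv")

        stage = "haplotypes"
        outputs["haplotypes"] = _write(
            collapse_haplotypes(ds), out_dir, "haplotypes.tsv"
        )

        stage = "structure"
        if len(ds.populations) >= 2:
            fst = structure.fst_matrix(ds, permutations=config.permutations,
                                       seed=config.seed)
            outputs["fst"] = _write(fst.to_frame(), out_dir, "fst.tsv")
            outputs["fst_p"] = _write(fst.pvalues_frame(), out_dir, "fst_pvalues.tsv")
            outputs["gene_flow"] = _write(
                structure.gene_flow_matrix(fst), out_dir, "gene_flow.tsv"
            )
            if len(ds.populations) >= 3:
                mds = structure.classical_mds(fst)
                outputs["mds"] = _write(mds.to_frame(), out_dir, "mds.tsv")
                logger.info("MDS stress %.4f", mds.stress)

        stage = "mismatch"
        rows = []
        for i, pop in enumerate(ds.populations):
            sub = ds.subset(pop)
            if sub.n < 3:
                logger.info("skipping mismatch for %s (n=%d)", pop, sub.n)
                continue
            spec = mismatch.mismatch_spectrum(sub)
            fit = mismatch.fit_expansion(spec, sub.n)
            if config.bootstraps:
                fit.p_ssd, fit.p_rag = mismatch.bootstrap_pvalues(
                    sub, fit, B=config.bootstraps, seed=config.seed + i
                )
            rows.append({"population": pop, "tau": fit.tau, "theta0": fit.theta0,
                         "theta1": fit.theta1, "SSD": fit.ssd, "p_SSD": fit.p_ssd,
                         "raggedness": fit.raggedness, "p_rag": fit.p_rag})
        if rows:
            outputs["mismatch"] = _write(
                pd.DataFrame(rows).set_index("population"), out_dir, "mismatch.tsv"
            )

        stage = "haplogroups"
        if config.tree_table:
            tree = haplogroups.load_tree_table(config.tree_table)
            calls = haplogroups.classify_dataset(ds.profiles, tree, ds.region_set)
            outputs["haplogroup_calls"] = _write(calls, out_dir, "haplogroup_calls.tsv")
            freqs = haplogroups.build_frequency_table(
                calls["haplogroup"].to_dict(), ds.pop_of
            )
            outputs["haplogroup_freqs"] = _write(
                freqs.freq, out_dir, "haplogroup_frequencies.tsv"
            )

        stage = "dating"
        if config.clades:
            clades = [
                dating.CladeGenealogy.from_newick(p, label=Path(p).stem)
                for p in config.clades
            ]
            outputs["dating"] = _write(dating.date_clades(clades), out_dir, "dating.tsv")

        stage = "network"
        if config.build_network:
            net = network.network_from_dataset(ds)
            outputs["network_nodes"] = _write(net.node_table(), out_dir,
                                              "network_nodes.tsv")
            outputs["network_edges"] = _write(
                net.edge_table().set_index("u"), out_dir, "network_edges.tsv"
            )
        logger.info("pipeline complete: %d reports", len(outputs))
        return outputs
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
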