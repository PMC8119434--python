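"""End-to-end orchestration: simulate -> assign-species -> triage ->
abundance -> srna-profile -> associate, from one config with deterministic
seeding and a consolidated report bundle.

Every stage output is a pure function of (inputs, config, seed); a rerun with
the same config and seed produces byte-identical files. Errors in one dataset
do not abort the study: the dataset is marked failed in the run manifest, as
in multi-dataset screening practice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import associate, composition, map_reads_exact, pca, tpm
from .contig_triage import triage
from .io_formats import PipelineConfig, SeqRecord, write_tables
from .species_assign import (SpeciesCall, assign_species, dataset_tree,
                             mtcoi_distance_matrix, references_from_fasta)
from .srna_profile import (ClassifyThresholds, build_profile, classify_profile,
                           clean_srna, detect_hotspots, map_srna,
                           pool_profiles)
from .synthetic_data import StudyBundle

logger = logging.getLogger("vectorvirome")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_digests: dict[str, str]
    stage_rows: dict[str, int]
    failed_datasets: dict[str, str]

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="ascii", newline="\n") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(records: list[SeqRecord]) -> str:
    h = hashlib.sha256()
    for rec in records:
        h.update(rec.id.encode())
        h.update(rec.seq.encode())
    return h.hexdigest()[:16]


@dataclass
class StudyResults:
    species_calls: dict[str, SpeciesCall]
    triage: pd.DataFrame
    passing: dict[str, list[SeqRecord]]     # dataset -> passing contigs
    abundance: pd.DataFrame                 # long: dataset, contig, b, c, tpm
    counts_by_virus: pd.DataFrame           # datasets x viruses, raw counts
    tpm_by_virus: pd.DataFrame              # datasets x viruses, TPM
    association: object
    pca: object | None
    profiles: pd.DataFrame
    five_prime: pd.DataFrame
    classifications: pd.DataFrame
    hotspots: pd.DataFrame
    tree_newick: str | None
    manifest: RunManifest


def run_study(bundle: StudyBundle, config: PipelineConfig,
              out_dir: str | Path | None = None) -> StudyResults:
    """Run every analysis stage over a study bundle and (optionally) write
    the consolidated report."""
    references = references_from_fasta(bundle.references)
    failed: dict[str, str] = {}
    species_calls: dict[str, SpeciesCall] = {}
    triage_rows = []
    passing: dict[str, list[SeqRecord]] = {}
    abundance_rows = []
    counts_by_virus: dict[str, dict[str, int]] = {}
    tpm_by_virus: dict[str, dict[str, float]] = {}
    profile_rows = []
    fp_rows = []
    class_rows = []
    hotspot_rows = []
    mtcoi_contigs: list[SeqRecord] = []
    digests: dict[str, str] = {}

    for ds in bundle.datasets:
        try:
            digests[ds.dataset_id] = _digest(ds.contigs_a)
            call = assign_species(ds.contigs_a, references,
                                  config.species_divergence_max,
                                  dataset_id=ds.dataset_id)
            species_calls[ds.dataset_id] = call
            if call.contig_id is not None:
                contig = next(c for c in ds.contigs_a if c.id == call.contig_id)
                mtcoi_contigs.append(
                    SeqRecord(ds.dataset_id, contig.seq))

            # every assembled contig is a candidate; those without homology
            # hits fail the E-value criterion
            candidates = list(ds.contigs_a)
            mapping = map_reads_exact(ds.reads, ds.contigs_a)
            decisions = triage(candidates, ds.hits, mapping.mapped_lengths(),
                               ds.contigs_b, config)
            passing[ds.dataset_id] = [
                c for c in candidates
                if next(d for d in decisions if d.contig_id == c.id).overall]
            for d in decisions:
                triage_rows.append({
                    "dataset_id": ds.dataset_id, "contig_id": d.contig_id,
                    "pass_evalue": d.pass_evalue, "pass_length": d.pass_length,
                    "pass_coverage": d.pass_coverage, "pass_orf": d.pass_orf,
                    "pass_cross_assembler": d.pass_cross_assembler,
                    "overall": d.overall,
                    "best_evalue": (d.best_hit.evalue if d.best_hit else
                                    float("nan")),
                    "mean_coverage": d.mean_coverage,
                })

            # abundance over the passing viral contigs only
            pass_contigs = passing[ds.dataset_id]
            if pass_contigs:
                vmap = map_reads_exact(ds.reads, pass_contigs)
                b = vmap.unique_counts()
                ids = [c.id for c in pass_contigs]
                bvec = [b.get(i, 0) for i in ids]
                cvec = [len(c.seq) for c in pass_contigs]
                avec = tpm(bvec, cvec)
                vcounts: dict[str, int] = {}
                vtpm: dict[str, float] = {}
                for cid, bj, cj, aj in zip(ids, bvec, cvec, avec):
                    abundance_rows.append({
                        "dataset_id": ds.dataset_id, "contig_id": cid,
                        "b_uniq_fragments": bj, "c_length": cj, "tpm": aj})
                    virus = bundle.contig_to_virus.get(cid, cid)
                    vcounts[virus] = vcounts.get(virus, 0) + bj
                    vtpm[virus] = vtpm.get(virus, 0.0) + float(aj)
                counts_by_virus[ds.dataset_id] = vcounts
                tpm_by_virus[ds.dataset_id] = vtpm

            # vsiRNA profiling against the passing contigs of the core virus
            srna = clean_srna(ds.srna, config.srna_len_min, config.srna_len_max)
            genomes = pass_contigs if pass_contigs else []
            if srna and genomes:
                smap = map_srna(srna, genomes)
                by_virus: dict[str, list] = {}
                for g in genomes:
                    by_virus.setdefault(
                        bundle.contig_to_virus.get(g.id, g.id), []).append(g)
                for virus, segs in sorted(by_virus.items()):
                    seg_profiles = [build_profile(smap, g) for g in segs]
                    prof = pool_profiles(seg_profiles, virus)
                    for size in prof.size_strand.index:
                        profile_rows.append({
                            "dataset_id": ds.dataset_id, "virus_id": virus,
                            "size": size,
                            "plus": int(prof.size_strand.loc[size, "plus"]),
                            "minus": int(prof.size_strand.loc[size, "minus"]),
                        })
                        fp_rows.append({
                            "dataset_id": ds.dataset_id, "virus_id": virus,
                            "size": size,
                            **{b: int(prof.five_prime.loc[size, b])
                               for b in "ACGU"}})
                    cls = classify_profile(
                        prof, ClassifyThresholds(min_reads=config.srna_min_reads))
                    class_rows.append({
                        "dataset_id": ds.dataset_id, "virus_id": virus,
                        "peak_size": cls.peak_size,
                        "plus_fraction": cls.plus_fraction,
                        "fiveprime_U_fraction": cls.fiveprime_U_fraction,
                        "label": cls.label})
                    for seg_prof in seg_profiles:
                        for strand, depth in (("plus", seg_prof.depth_plus),
                                              ("minus", seg_prof.depth_minus)):
                            if len(depth) < 10:
                                continue
                            for start, end in detect_hotspots(depth):
                                hotspot_rows.append({
                                    "dataset_id": ds.dataset_id,
                                    "virus_id": virus,
                                    "segment": seg_prof.virus_id,
                                    "strand": strand,
                                    "start": start, "end": end})
        except Exception as exc:  # keep screening the remaining datasets
            logger.exception("dataset %s failed", ds.dataset_id)
            failed[ds.dataset_id] = f"{type(exc).__name__}: {exc}"

    all_viruses = sorted({v for d in counts_by_virus.values() for v in d})
    ds_ids = sorted(counts_by_virus)
    counts_df = pd.DataFrame(
        [[counts_by_virus[d].get(v, 0) for v in all_viruses] for d in ds_ids],
        index=ds_ids, columns=all_viruses)
    tpm_df = pd.DataFrame(
        [[tpm_by_virus[d].get(v, 0.0) for v in all_viruses] for d in ds_ids],
        index=ds_ids, columns=all_viruses)

    association = None
    pca_res = None
    if not counts_df.empty:
        association = associate(species_calls, tpm_df, counts_df,
                                config.detection_floor_tpm)
        if counts_df.shape[0] >= 2 and counts_df.shape[1] >= 2:
            pca_res = pca(tpm_df)

    tree = None
    if len(mtcoi_contigs) >= 3:
        dm = mtcoi_distance_matrix(mtcoi_contigs)
        tree = dataset_tree([c.id for c in mtcoi_contigs], dm)

    manifest = RunManifest(
        config=dataclasses.asdict(config), seed=config.rng_seed,
        version=__version__, input_digests=digests,
        stage_rows={"species_calls": len(species_calls),
                    "triage": len(triage_rows),
                    "abundance": len(abundance_rows),
                    "profiles": len(class_rows)},
        failed_datasets=failed)

    results = StudyResults(
        species_calls=species_calls,
        triage=pd.DataFrame(triage_rows),
        passing=passing,
        abundance=pd.DataFrame(abundance_rows),
        counts_by_virus=counts_df,
        tpm_by_virus=tpm_df,
        association=association,
        pca=pca_res,
        profiles=pd.DataFrame(profile_rows),
        five_prime=pd.DataFrame(fp_rows),
        classifications=pd.DataFrame(class_rows),
        hotspots=pd.DataFrame(hotspot_rows),
        tree_newick=tree,
        manifest=manifest)

    if out_dir is not None:
        write_results(results, out_dir)
    return results


def write_results(results: StudyResults, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calls_df = pd.DataFrame([
        {"dataset_id": c.dataset_id, "contig_id": c.contig_id or "",
         "best_reference_id": c.best_reference_id or "",
         "species": c.species_label,
         "divergence": c.divergence if c.divergence is not None else float("nan"),
         "within_threshold": ",".join(c.within_threshold_labels)}
        for c in results.species_calls.values()])
    comp_rows = []
    for ds in results.counts_by_virus.index:
        comp = composition(results.counts_by_virus.loc[ds].to_dict())
        for virus, share in sorted(comp.shares.items()):
            comp_rows.append({"dataset_id": ds, "virus_id": virus,
                              "share": share,
                              "dominant": virus == comp.dominant})
    tables: dict = {
        "species_calls": calls_df,
        "triage": results.triage,
        "abundance": results.abundance,
        "composition": pd.DataFrame(comp_rows),
        "srna_profile": results.profiles,
        "five_prime": results.five_prime,
        "classification": results.classifications,
        "hotspots": results.hotspots,
    }
    if results.association is not None:
        assoc = results.association.presence.reset_index(names="virus_id")
        assoc["class"] = [results.association.virus_class[v]
                          for v in assoc["virus_id"]]
        tables["association"] = assoc
    if results.pca is not None:
        tables["pca_scores"] = results.pca.scores.reset_index(
            names="dataset_id")
    if results.tree_newick is not None:
        tables["tree_newick"] = results.tree_newick
    all_passing = [c for ds in sorted(results.passing)
                   for c in results.passing[ds]]
    seen: set[str] = set()
    uniq = []
    for c in all_passing:
        if c.id not in seen:
            seen.add(c.id)
            uniq.append(c)
    tables["passing_contigs"] = uniq
    write_tables(tables, out_dir)
    results.manifest.write(out_dir / "manifest.json")


def run_all(config: PipelineConfig, out_dir: str | Path,
            bundle: StudyBundle | None = None) -> StudyResults:
    """Simulate (unless a bundle is supplied) and run every stage."""
    from .synthetic_data import gen_study

    if bundle is None:
        bundle = gen_study(seed=config.rng_seed)
    return run_study(bundle, config, out_dir)
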