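"""End-to-end orchestration: simulate -> dedup -> scan -> cluster -> context -> stats.

A run is fully reproducible: one global seed is fanned out into per-stage
substreams (so rerunning with the same config and seed yields byte-identical
TSV outputs), and a manifest records the configuration, per-stage row
counts, warnings and a SHA-256 digest of every output file.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, dataset_io, genome_context, netstats, profile_scan, seqcluster
from . import synthetic_genomes as sg


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Run parameters.  Paper-stated defaults are kept: profile-inclusion
    E-value 0.01, inter-gene distance cutoff 100 nt, size-class landmarks
    25/100/180 kb."""

    seed: int = 0
    n_genomes: int = 200
    inclusion_E: float = 0.01
    max_iter: int = 5
    gap_cutoff: int = 100
    window: int = 5
    min_support: int = 3
    min_taxa: int = 2
    density_threshold: float = 0.8
    coverage_threshold: float = 0.6
    coverage_mode: str = "both"
    overlap_frac: float = 0.5
    taxid_dup_prob: float = 0.05
    families: tuple[str, ...] = tuple(sorted(sg.DEFAULT_FAMILY_PARAMS))
    network_families: tuple[str, ...] = sg.DEFAULT_NETWORK_FAMILIES
    cooccur_families: tuple[str, ...] = ("Macro", "NADAR", "SLOG", "Nudix")
    prevalence_thresholds: tuple[float, ...] = tuple(
        float(t) for t in (0, 5e3, 10e3, 17.5e3, 25e3, 40e3, 60e3, 100e3, 140e3, 180e3, 250e3)
    )
    genome_length_scale: float = 1.0  # multiplies the generator's length medians

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("families", "network_families", "cooccur_families", "prevalence_thresholds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["prevalence_thresholds"] = list(self.prevalence_thresholds)
        for key in ("families", "network_families", "cooccur_families"):
            d[key] = list(d[key])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _generator_config(config: PipelineConfig, seed: int) -> sg.GeneratorConfig:
    fam_params = {f: sg.DEFAULT_FAMILY_PARAMS[f] for f in config.families}
    length_model = dict(sg.DEFAULT_LENGTH_MODEL)
    if config.genome_length_scale != 1.0:
        length_model = {
            k: (kind, mu + np.log(config.genome_length_scale), sd)
            for k, (kind, mu, sd) in length_model.items()
        }
    rules = tuple(
        r for r in sg.DEFAULT_CONTEXT_RULES
        if r.anchor in config.families and r.partner in config.families
    )
    return sg.GeneratorConfig(
        n_genomes=config.n_genomes,
        seed=seed,
        family_params=fam_params,
        context_params=rules,
        length_model=length_model,
        network_families=tuple(f for f in config.network_families if f in config.families),
        taxid_dup_prob=config.taxid_dup_prob,
    )


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute all stages into ``out_dir``; returns the run directory.

    Any stage failure raises :class:`PipelineError` naming the stage; the
    manifest written so far is preserved and marked partial.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("simulate", "scan"), np.random.SeedSequence(config.seed).spawn(2)
        )
    }
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
        "warnings": [],
        "complete": False,
    }
    caught: list[str] = []

    def finish_stage(name: str, rows: dict[str, int]) -> None:
        manifest["stages"].append({"stage": name, "rows": rows})
        _write_manifest(out, manifest)

    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            _run_stages(config, out, stage_seeds, manifest, finish_stage)
            caught = [str(w.message) for w in wlist]
    except PipelineError:
        _write_manifest(out, manifest)
        raise
    except Exception as exc:  # attribute unexpected failures to the last stage
        _write_manifest(out, manifest)
        raise PipelineError("internal", exc) from exc

    manifest["warnings"] = caught
    manifest["complete"] = True
    manifest["files"] = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _run_stages(config, out, stage_seeds, manifest, finish_stage) -> None:
    # 1. simulate ----------------------------------------------------------
    try:
        gen_cfg = _generator_config(config, stage_seeds["simulate"])
        collection, truth = sg.generate_collection(gen_cfg)
        dataset_io.write_collection(collection, out / "collection")
        sg.write_truth(truth, out / "collection" / "truth")
    except Exception as exc:
        raise PipelineError("simulate", exc) from exc
    finish_stage("simulate", {"genomes": len(collection.genomes), "proteins": len(collection.proteins)})

    # 2. dedup -------------------------------------------------------------
    try:
        collection, dropped = dataset_io.deduplicate_by_taxid(collection)
        dataset_io.write_collection(collection, out / "dedup")
        (out / "dedup" / "dropped_genomes.txt").write_text(
            "".join(f"{g}\n" for g in dropped)
        )
    except Exception as exc:
        raise PipelineError("dedup", exc) from exc
    finish_stage("dedup", {"genomes": len(collection.genomes), "dropped": len(dropped)})

    # 3. scan --------------------------------------------------------------
    try:
        all_hits: list[profile_scan.DomainHit] = []
        candidates: list[profile_scan.DomainHit] = []
        non_converged: list[str] = []
        scan_rng = np.random.default_rng(stage_seeds["scan"])
        for fam in config.families:
            profile = profile_scan.build_profile(
                sg.seed_alignment(fam), pseudocount_weight=0.5, family_id=fam
            )
            result = profile_scan.iterative_search(
                profile,
                collection,
                inclusion_E=config.inclusion_E,
                max_iter=config.max_iter,
                seed=scan_rng,
            )
            all_hits.extend(result.hits)
            candidates.extend(result.candidates)
            if not result.converged:
                warnings.warn(f"profile {fam}: inclusion set still growing at max_iter")
                non_converged.append(fam)
        profile_scan.write_hits(
            sorted(all_hits, key=lambda h: (h.protein_id, h.family_id)), out / "hits.tsv"
        )
        profile_scan.write_hits(
            sorted(candidates, key=lambda h: (h.protein_id, h.family_id)),
            out / "candidate_hits.tsv",
        )
    except Exception as exc:
        raise PipelineError("scan", exc) from exc
    finish_stage("scan", {"hits": len(all_hits), "candidates": len(candidates),
                          "non_converged_profiles": len(non_converged)})

    # 4. cluster (detected domain segments) --------------------------------
    try:
        params = seqcluster.ScoringParams(
            density_threshold=config.density_threshold,
            coverage_threshold=config.coverage_threshold,
            coverage_mode=config.coverage_mode,
        )
        segments = {
            f"{h.protein_id}:{h.ali_start}-{h.ali_end}": collection.protein(
                h.protein_id
            ).sequence[h.ali_start - 1 : h.ali_end]
            for h in all_hits
        }
        clusters = seqcluster.cluster(segments, params)
        seqcluster.write_clusters(clusters, out / "clusters.tsv")
    except Exception as exc:
        raise PipelineError("cluster", exc) from exc
    finish_stage("cluster", {"segments": len(segments), "clusters": len(clusters)})

    # 5. context -----------------------------------------------------------
    try:
        architectures = genome_context.detect_architectures(all_hits, config.overlap_frac)
        annotations = {a.protein_id: frozenset(a.families) for a in architectures}
        anchors = sorted(annotations)
        neighborhoods = genome_context.extract_neighborhoods(
            collection, anchors, window=config.window, gap_cutoff=config.gap_cutoff
        )
        contexts = genome_context.mine_contexts(
            neighborhoods,
            annotations,
            collection.genome_taxids,
            min_support=config.min_support,
            min_taxa=config.min_taxa,
        )
        genome_context.contexts_to_frame(contexts).to_csv(
            out / "contexts.tsv", sep="\t", index=False, lineterminator="\n"
        )
        pd.DataFrame(
            [
                {"protein_id": a.protein_id, "architecture": a.architecture_string}
                for a in architectures
            ],
            columns=["protein_id", "architecture"],
        ).to_csv(out / "architectures.tsv", sep="\t", index=False, lineterminator="\n")
    except Exception as exc:
        raise PipelineError("context", exc) from exc
    finish_stage("context", {"neighborhoods": len(neighborhoods), "contexts": len(contexts)})

    # 6. stats -------------------------------------------------------------
    try:
        network = set(config.network_families)
        carriage: dict[str, set] = {g.genome_id: set() for g in collection.genomes}
        for h in all_hits:
            carriage[collection.protein(h.protein_id).genome_id].add(h.family_id)
        positives = {g for g, fams in carriage.items() if fams & network}

        dna = [g for g in collection.genomes if g.na_class not in sg.RNA_CLASSES]
        rna = [g for g in collection.genomes if g.na_class in sg.RNA_CLASSES]
        curves = []
        for label, subset in (("DNA", dna), ("RNA", rna)):
            cur = netstats.prevalence_curve(subset, positives, config.prevalence_thresholds)
            cur.insert(0, "genome_group", label)
            curves.append(cur)
        pd.concat(curves, ignore_index=True).to_csv(
            out / "prevalence_curve.tsv", sep="\t", index=False, lineterminator="\n"
        )

        netstats.class_prevalence(collection.genomes, positives).to_csv(
            out / "class_prevalence.tsv", sep="\t", index=False, lineterminator="\n"
        )

        phages = [g for g in collection.genomes
                  if g.morphology in ("myovirus", "siphovirus", "podovirus")]
        netstats.per_1000(phages, positives).to_csv(
            out / "per_1000.tsv", sep="\t", index=False, lineterminator="\n"
        )

        enr_rows = []
        table = []
        for m in ("myovirus", "siphovirus", "podovirus"):
            n = sum(1 for g in phages if g.morphology == m)
            npos = sum(1 for g in phages if g.morphology == m and g.genome_id in positives)
            if n > 0:
                table.append([npos, n - npos])
        if len(table) >= 2 and positives:
            try:
                res = netstats.enrichment_test(table)
                enr_rows.append(
                    {"test": "morphology_x_network", "chi2": res.chi2, "df": res.df,
                     "p_value": res.p_value, "low_expected": int(res.low_expected)}
                )
            except ValueError as exc:
                warnings.warn(f"morphology enrichment skipped: {exc}")
        pd.DataFrame(
            enr_rows, columns=["test", "chi2", "df", "p_value", "low_expected"]
        ).to_csv(out / "enrichment.tsv", sep="\t", index=False, lineterminator="\n")

        dna_ids = [g.genome_id for g in dna]
        cooc = netstats.cooccurrence(carriage, list(config.cooccur_families), stratum=dna_ids)
        netstats.cooccurrence_to_frame(cooc).to_csv(
            out / "cooccurrence.tsv", sep="\t", index=False, lineterminator="\n"
        )
        euler = netstats.euler_counts(carriage, list(config.cooccur_families), stratum=dna_ids)
        pd.DataFrame(
            [{"families": "&".join(k), "n_genomes": v} for k, v in sorted(euler.items())],
            columns=["families", "n_genomes"],
        ).to_csv(out / "euler_counts.tsv", sep="\t", index=False, lineterminator="\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("stats", exc) from exc
    finish_stage(
        "stats",
        {"positives": len(positives), "cooccurrence_pairs": len(cooc), "euler_regions": len(euler)},
    )
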