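"""End-to-end orchestration: ingest -> annotate -> group -> compare ->
filter -> distributions -> reports.

The pipeline reads a directory of assembly files plus a chain-protein
mapping table, applies the entry and interface filters, builds the
redundancy hierarchy and emits the three similarity distributions (and,
when requested, their homomer-filtered variants) together with a pairwise
comparison table and a manifest recording the attrition at every stage.
All randomness (Interolog subsampling caps, bootstrap) is driven by one
seed recorded in the manifest, so a rerun reproduces every output byte for
byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import distributions as dist
from .annotation import (
    AnnotationConfig,
    annotate_interface,
    annotation_rows,
    assign_copy_numbers,
    passes_size_filter,
)
from .engine import PairwiseComparer
from .grouping import build_hierarchy, eligible_groups, hierarchy_rows
from .homomer import filtered_distributions
from .model import Assembly, HeteroDimer, ProteinMapping
from .similarity import MEASURES
from .structures import (
    extract_hetero_dimers,
    load_assembly,
    passes_entry_filter,
    read_mapping,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str
    mapping_path: str
    distance_cutoff: float = 6.0
    use_dasa: bool = True
    max_resolution: float = 2.5
    require_xray: bool = True
    min_face_size: int = 5
    min_coverage: float = 0.3
    measures: tuple[str, ...] = MEASURES
    caps: tuple[int, int] = (50, 50)
    include_intra_assembly: bool = True  # compare copies within one assembly
    homomer_mode: str = "off"  # 'off', 'sequence' or 'structural'
    n_boot: int = 200
    seed: int = 0
    report_threshold: float = 0.9

    def __post_init__(self) -> None:
        for name in ("distance_cutoff", "max_resolution", "min_face_size"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")


@dataclass
class RunResult:
    config: RunConfig
    assemblies: dict[str, Assembly]
    dimers: list[HeteroDimer]
    forest: list
    comparers: dict[str, PairwiseComparer]
    distributions: dict[str, dict[str, dist.Distribution]]
    filtered: dict[str, dict[str, dist.Distribution]]
    manifest: dict
    records: pd.DataFrame = field(default=None)


def _load_inputs(config: RunConfig):
    input_dir = Path(config.input_dir)
    mapping = read_mapping(config.mapping_path)
    paths = sorted(
        p
        for p in input_dir.iterdir()
        if p.suffix.lower() in (".pdb", ".ent", ".cif", ".mmcif")
    )
    assemblies = []
    for path in paths:
        try:
            assemblies.append(load_assembly(path))
        except Exception as exc:  # unparseable file: skip, keep going
            log.warning("skipping %s: %s", path.name, exc)
    return assemblies, mapping


def prepare_dimers(
    assemblies: list[Assembly],
    mapping: ProteinMapping,
    config: RunConfig,
    manifest: dict,
) -> tuple[dict[str, Assembly], list[HeteroDimer]]:
    """Entry filter, dimer extraction, annotation, size filter, copy numbers."""
    manifest["entries_read"] = len(assemblies)
    retained = [
        a
        for a in assemblies
        if passes_entry_filter(
            a, mapping, config.max_resolution, config.require_xray
        )
    ]
    manifest["entries_passing_filter"] = len(retained)
    ann_config = AnnotationConfig(
        distance_cutoff=config.distance_cutoff,
        use_dasa=config.use_dasa,
        min_face_size=config.min_face_size,
    )
    kept: list[HeteroDimer] = []
    n_extracted = 0
    n_skipped = 0
    for assembly in retained:
        dimers = extract_hetero_dimers(assembly, mapping, config.distance_cutoff)
        n_extracted += len(dimers)
        surviving = []
        for dimer in dimers:
            try:
                dimer.interface = annotate_interface(dimer, ann_config)
            except Exception as exc:
                log.warning("annotation failed for %s: %s", dimer.uid, exc)
                n_skipped += 1
                continue
            if passes_size_filter(dimer.interface, config.min_face_size):
                surviving.append(dimer)
        assign_copy_numbers(surviving)
        kept.extend(surviving)
    manifest["dimers_extracted"] = n_extracted
    manifest["dimers_annotation_failed"] = n_skipped
    manifest["dimers_passing_size_filter"] = len(kept)
    return {a.assembly_id: a for a in retained}, kept


def run(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline; write outputs when ``out_dir`` is given."""
    manifest: dict = {"config": _config_dict(config)}
    assemblies, mapping = _load_inputs(config)
    assembly_map, dimers = prepare_dimers(assemblies, mapping, config, manifest)
    forest = build_hierarchy(dimers)
    manifest["eligible_groups"] = {
        level: len(eligible_groups(forest, level))
        for level in ("SameSeq", "SameProt", "Interolog")
    }

    families = {key: entry.family for key, entry in mapping.entries.items()}
    comparers: dict[str, PairwiseComparer] = {}
    results: dict[str, dict[str, dist.Distribution]] = {}
    filtered: dict[str, dict[str, dist.Distribution]] = {}
    for measure in config.measures:
        comparer = PairwiseComparer(
            dimers,
            assemblies=assembly_map,
            measure=measure,
            measures=config.measures,
            min_coverage=config.min_coverage,
            families=families,
            include_intra_assembly=config.include_intra_assembly,
        )
        comparers[measure] = comparer
        bins = dist.fps_bins() if measure == "fps" else dist.lrms_bins()
        results[measure] = {}
        for level, func in (
            ("SameSeq", dist.d_sameseq),
            ("SameProt", dist.d_sameprot),
            ("Interolog", dist.d_interolog),
        ):
            try:
                if func is dist.d_interolog:
                    d = func(forest, comparer, bins, caps=config.caps,
                             n_boot=config.n_boot, seed=config.seed)
                else:
                    d = func(forest, comparer, bins,
                             n_boot=config.n_boot, seed=config.seed)
            except dist.UndefinedDistributionError:
                log.warning("D-%s undefined for %s", level, measure)
                d = None
            results[measure][level] = d
        if config.homomer_mode != "off":
            try:
                filtered[measure] = filtered_distributions(
                    forest, comparer, bins, mode=config.homomer_mode,
                    caps=config.caps, n_boot=config.n_boot, seed=config.seed,
                )
            except dist.UndefinedDistributionError:
                filtered[measure] = {}

    records = comparison_table(forest, comparers, config)
    manifest["comparisons_computed"] = int(len(records))
    manifest["seed"] = config.seed
    result = RunResult(
        config=config,
        assemblies=assembly_map,
        dimers=dimers,
        forest=forest,
        comparers=comparers,
        distributions=results,
        filtered=filtered,
        manifest=manifest,
        records=records,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["measures"] = list(config.measures)
    d["caps"] = list(config.caps)
    return d


def _level_of(dimer_a: HeteroDimer, dimer_b: HeteroDimer) -> str:
    if dimer_a.seq_pair == dimer_b.seq_pair:
        return "SameSeq"
    if dimer_a.prot_pair == dimer_b.prot_pair:
        return "SameProt"
    return "Interolog"


def comparison_table(
    forest, comparers: dict[str, PairwiseComparer], config: RunConfig
) -> pd.DataFrame:
    """Pairwise-comparison table over every within-Interolog-group pair.

    One row per compared dimer pair with all measure values, copy numbers,
    the best-homomer-match indicator (when a homomer mode is configured)
    and the type of sequence divergence between the two dimers.
    """
    fps_comparer = comparers.get("fps") or next(iter(comparers.values()))
    filter_comparer = (
        fps_comparer.with_homomer_mode(config.homomer_mode)
        if config.homomer_mode != "off"
        else None
    )
    rows = []
    for group in forest:
        members = group.members()
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                rec = fps_comparer.record(a, b)
                if rec is None:
                    continue
                row = {
                    "dimerA": a.uid,
                    "dimerB": b.uid,
                    "fps": rec.fps,
                    "fps_X": rec.fps_X,
                    "fps_Y": rec.fps_Y,
                    "l_rms": rec.l_rms,
                    "i_rms": rec.i_rms,
                    "copy_number_A": a.copy_number,
                    "copy_number_B": b.copy_number,
                    "level": _level_of(a, b),
                    "intra_assembly": rec.intra_assembly,
                }
                if filter_comparer is not None:
                    row["best_homomer_match"] = (
                        filter_comparer.compare(a, b) is not None
                    )
                rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["dimerA", "dimerB"]).reset_index(drop=True)
    return frame


def report_divergent_pairs(
    records: pd.DataFrame, threshold: float = 0.9
) -> pd.DataFrame:
    """All compared pairs with Face Position Similarity below the threshold,
    most divergent first."""
    if records.empty:
        return records
    out = records[records["fps"] < threshold]
    return out.sort_values(["fps", "dimerA", "dimerB"]).reset_index(drop=True)


def write_outputs(result: RunResult, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for measure, by_level in result.distributions.items():
        for level, d in by_level.items():
            if d is None:
                continue
            frame = pd.DataFrame(d.rows())
            frame.to_csv(
                out_dir / f"distribution_{measure}_{level}.tsv",
                sep="\t", index=False, float_format="%.6f",
            )
    for measure, by_level in result.filtered.items():
        for level, d in by_level.items():
            if d is None:
                continue
            pd.DataFrame(d.rows()).to_csv(
                out_dir / f"distribution_{measure}_{level}_homomer_filtered.tsv",
                sep="\t", index=False, float_format="%.6f",
            )
    if result.records is not None and not result.records.empty:
        result.records.to_csv(
            out_dir / "comparisons.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
        report = report_divergent_pairs(
            result.records, result.config.report_threshold
        )
        report.to_csv(
            out_dir / "divergent_pairs.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
    annotations = [row for d in result.dimers for row in annotation_rows(d)]
    pd.DataFrame(annotations).to_csv(
        out_dir / "interfaces.tsv", sep="\t", index=False, float_format="%.6f"
    )
    pd.DataFrame(hierarchy_rows(result.forest)).to_csv(
        out_dir / "hierarchy.tsv", sep="\t", index=False
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
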