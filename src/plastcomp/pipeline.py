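"""Pipeline orchestration: run every analysis stage over a set of plastome
records against a declared reference and emit plain TSV tables (region
sizes, SSRs, repeats, substitution summaries, Ka/Ks, codon usage, junction
reports, binned hotspot correlation / co-occurrence).

Every output table begins with comment lines naming the producing stage,
the parameters used and a hash of the configuration, so a rerun with the
same config is byte-identical and diffable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment import (
    align_near_identical,
    concatenate_genes,
    extract_events,
    summarize_substitutions,
)
from .hotspots import bin_events, correlation_report
from .junctions import junction_report
from .records import PlastomeRecord, read_plastome
from .repeats import find_oligo_repeats, summarize_repeat_kinds
from .selection import codon_profile, gene_selection
from .ssr import classify_ssrs, find_ssrs, ssr_table
from .structure import detect_and_normalize, gene_census, region_stats


@dataclass
class PipelineConfig:
    inputs: list[str] = field(default_factory=list)  # file paths
    reference: str | None = None  # id or path of the reference record
    input_format: str = "auto"
    out_dir: str = "plastcomp_out"
    min_ir_len: int = 10_000
    ir_min_identity: float = 0.99
    ssr_thresholds: dict[int, int] | None = None
    repeat_min_len: int = 30
    repeat_min_identity: float = 0.90
    bin_size: int = 250
    junction_window: int = 2000
    kaks_genes: list[str] | None = None  # explicit include list; None = all CDS
    kaks_exclude: list[str] = field(default_factory=list)
    cooccurrence_bin_level: bool = False
    stages: list[str] = field(
        default_factory=lambda: [
            "structure", "ssr", "repeats", "codon", "junctions",
            "events", "kaks", "hotspots",
        ]
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ssr_thresholds" in raw and raw["ssr_thresholds"]:
            raw["ssr_thresholds"] = {int(k): int(v) for k, v in raw["ssr_thresholds"].items()}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def _write_table(df: pd.DataFrame, path: Path, stage: str, params: dict, cfg_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n")
        fh.write(f"# params: {json.dumps(params, sort_keys=True, default=str)}\n")
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, records: list[PlastomeRecord] | None = None) -> dict:
    """Run the configured stages; returns {table name: DataFrame} and writes
    each table under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    if records is None:
        records = [read_plastome(p, format=config.input_format) for p in config.inputs]
    if not records:
        raise StageError("input", ValueError("no input records"))

    normalized: dict[str, tuple] = {}
    for rec in records:
        try:
            nrec, st = detect_and_normalize(rec, config.min_ir_len, config.ir_min_identity)
        except Exception as exc:  # noqa: BLE001
            raise StageError("structure", exc) from exc
        normalized[rec.id] = (nrec, st)

    ref_id = config.reference
    if ref_id is None:
        ref_id = records[0].id
    elif ref_id not in normalized:
        # allow a path as reference designator
        ref_id = Path(ref_id).stem if Path(ref_id).stem in normalized else ref_id
    if ref_id not in normalized:
        raise StageError("input", KeyError(f"reference {config.reference!r} not among inputs"))
    ref_rec, ref_st = normalized[ref_id]

    tables: dict[str, pd.DataFrame] = {}
    stages = set(config.stages)

    if "structure" in stages:
        rows = []
        for rid, (nrec, st) in normalized.items():
            rs = region_stats(nrec, st)
            cen = gene_census(nrec, st)
            rows.append(
                {
                    "species": rid,
                    "total": rs.total_length,
                    "LSC": rs.lengths["LSC"],
                    "SSC": rs.lengths["SSC"],
                    "IR": rs.lengths["IRb"],
                    "gc_total": round(rs.total_gc, 4),
                    "unique_genes": cen.unique_genes,
                    "duplicated_in_ir": cen.duplicated_in_ir,
                    "total_genes": cen.total_genes,
                    "source": nrec.source,
                }
            )
        tables["regions"] = pd.DataFrame(rows)
        _write_table(tables["regions"], out / "regions.tsv", "structure",
                     {"min_ir_len": config.min_ir_len, "min_identity": config.ir_min_identity}, h)

    repeats_by_id = {}
    for rid, (nrec, st) in normalized.items():
        if "ssr" in stages:
            loci = classify_ssrs(find_ssrs(nrec, config.ssr_thresholds), st, nrec.annotations)
            df = ssr_table(loci)
            tables[f"ssr_{rid}"] = df
            _write_table(df, out / f"ssr_{rid}.tsv", "ssr",
                         {"thresholds": config.ssr_thresholds or "default"}, h)
        if "repeats" in stages or "hotspots" in stages:
            reps = find_oligo_repeats(
                nrec, config.repeat_min_len, config.repeat_min_identity, structure=st
            )
            repeats_by_id[rid] = reps
            if "repeats" in stages:
                df = pd.DataFrame(
                    [
                        {
                            "kind": r.kind, "length": r.length, "pos1": r.pos1,
                            "pos2": r.pos2, "identity": r.identity,
                            "mismatches": r.mismatches, "is_genomic_ir": r.is_genomic_ir,
                        }
                        for r in reps
                    ]
                )
                tables[f"repeats_{rid}"] = df
                _write_table(df, out / f"repeats_{rid}.tsv", "repeats",
                             {"min_len": config.repeat_min_len,
                              "min_identity": config.repeat_min_identity}, h)
        if "codon" in stages:
            cds = _cds_set(nrec)
            if cds:
                prof = codon_profile(cds)
                df = pd.DataFrame(
                    sorted(
                        (
                            {"codon": c, "amino_acid": _aa(c), "count": prof.codon_counts[c],
                             "rscu": round(prof.rscu.get(c, float("nan")), 4)}
                            for c in prof.codon_counts
                        ),
                        key=lambda r: r["codon"],
                    )
                )
                tables[f"codon_{rid}"] = df
                _write_table(df, out / f"codon_{rid}.tsv", "codon", {}, h)
        if "junctions" in stages:
            entries = junction_report(nrec, st, window=config.junction_window)
            df = pd.DataFrame(
                [
                    {"junction": e.junction, "gene": e.gene, "relation": e.relation,
                     "side_a_bp": e.side_a_bp, "side_b_bp": e.side_b_bp,
                     "pseudogene": e.pseudogene}
                    for e in entries
                ]
            )
            tables[f"junctions_{rid}"] = df
            _write_table(df, out / f"junctions_{rid}.tsv", "junctions",
                         {"window": config.junction_window}, h)

    pair_ids = [rid for rid in normalized if rid != ref_id]
    needs_pairs = stages & {"events", "kaks", "hotspots"}
    sub_rows, kaks_frames, hot_rows = [], [], []
    for rid in pair_ids if needs_pairs else []:
        qry_rec, _ = normalized[rid]
        genes = _kaks_gene_list(config, ref_rec, qry_rec)
        if "events" in stages or "hotspots" in stages:
            ref_cat = concatenate_genes(ref_rec, genes) if genes else ref_rec.sequence
            qry_cat = concatenate_genes(qry_rec, genes) if genes else qry_rec.sequence
            try:
                aln = align_near_identical(ref_cat, qry_cat, ref_id=ref_id, qry_id=rid)
            except Exception as exc:  # noqa: BLE001
                raise StageError("events", exc) from exc
            subs, indels = extract_events(aln)
            summ = summarize_substitutions(subs)
            if "events" in stages:
                row = {"species": rid, **summ.counts, "Ts": summ.ts_count,
                       "Tv": summ.tv_count,
                       "Ts/Tv": summ.ts_tv_ratio if summ.ts_tv_ratio is not None else "NA"}
                sub_rows.append(row)
        if "kaks" in stages and genes:
            ests = []
            for g in genes:
                try:
                    est = gene_selection(
                        g, _gene_cds(ref_rec, g), _gene_cds(qry_rec, g)
                    )
                except Exception:  # noqa: BLE001  (per-gene failure is data, not fatal)
                    continue
                ests.append(
                    {"species": rid, "gene": g,
                     "ka": _r6(est.ka), "ks": _r6(est.ks),
                     "ratio": _r6(est.ratio), "category": est.category}
                )
            kaks_frames.append(pd.DataFrame(ests))
        if "hotspots" in stages:
            aln_g = align_near_identical(
                ref_rec.sequence, qry_rec.sequence, ref_id=ref_id, qry_id=rid
            )
            subs_g, indels_g = extract_events(aln_g)
            reps = [r for r in repeats_by_id.get(ref_id, []) if not r.is_genomic_ir]
            tracks = bin_events(
                subs_g, indels_g, reps, ref_rec.length, config.bin_size, ref_id=ref_id
            )
            rep = correlation_report(tracks, bin_level=config.cooccurrence_bin_level)
            hot_rows.append(
                {"species": rid,
                 "r_sub_indel": rep.r_sub_indel, "label_sub_indel": rep.label_sub_indel,
                 "r_indel_repeat": rep.r_indel_repeat, "label_indel_repeat": rep.label_indel_repeat,
                 "r_sub_repeat": rep.r_sub_repeat, "label_sub_repeat": rep.label_sub_repeat,
                 "subs_with_indels_pct": rep.cooccur_sub_with_indel,
                 "indels_with_repeats_pct": rep.cooccur_indel_with_repeat,
                 "subs_with_repeats_pct": rep.cooccur_sub_with_repeat}
            )
    if sub_rows:
        tables["substitutions"] = pd.DataFrame(sub_rows)
        _write_table(tables["substitutions"], out / "substitutions.tsv", "events",
                     {"reference": ref_id}, h)
    if kaks_frames:
        tables["kaks"] = pd.concat(kaks_frames, ignore_index=True)
        _write_table(tables["kaks"], out / "kaks.tsv", "kaks", {"reference": ref_id}, h)
    if hot_rows:
        tables["hotspots"] = pd.DataFrame(hot_rows)
        _write_table(tables["hotspots"], out / "hotspots.tsv", "hotspots",
                     {"reference": ref_id, "bin_size": config.bin_size,
                      "cooccurrence": "bin" if config.cooccurrence_bin_level else "event"}, h)

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"plastcomp {__version__}\n")
        fh.write(f"config_hash: {h}\n")
        fh.write(json.dumps(asdict(config), sort_keys=True, indent=2, default=str) + "\n")
    return tables


def _aa(codon: str) -> str:
    from .selection import CODON_TO_AA

    return CODON_TO_AA.get(codon, "?")


def _r6(v):
    return round(v, 6) if isinstance(v, float) else ("NA" if v is None else v)


def _cds_set(rec: PlastomeRecord) -> list[str]:
    out = []
    seen = set()
    for ann in rec.annotations:
        if ann.category != "protein_coding" or "pseudogene" in ann.notes:
            continue
        if ann.name in seen:
            continue
        seen.add(ann.name)
        cds = _gene_cds(rec, ann.name)
        if len(cds) % 3 == 0:
            out.append(cds)
    return out


def _gene_cds(rec: PlastomeRecord, gene: str) -> str:
    return concatenate_genes(rec, [gene])


def _kaks_gene_list(config: PipelineConfig, ref: PlastomeRecord, qry: PlastomeRecord) -> list[str]:
    if config.kaks_genes is not None:
        genes = list(config.kaks_genes)
    else:
        ref_names = {
            a.name for a in ref.annotations
            if a.category == "protein_coding" and "pseudogene" not in a.notes
        }
        qry_names = {
            a.name for a in qry.annotations
            if a.category == "protein_coding" and "pseudogene" not in a.notes
        }
        genes = sorted(ref_names & qry_names)
    return [g for g in genes if g not in set(config.kaks_exclude)]


def compare_to_reference_tables(
    produced: str | Path | pd.DataFrame,
    expected: str | Path | pd.DataFrame,
    int_exact: bool = True,
    ratio_tol: float = 0.005,
    pct_tol: float = 0.01,
) -> pd.DataFrame:
    """Cell-by-cell diff of two tables in the pipeline's TSV schema.

    Integer cells must match exactly; columns whose name mentions a ratio
    get ``ratio_tol``; percentage columns get ``pct_tol``. Returns a
    DataFrame of differing cells (empty when the tables agree).
    """
    a = _load_table(produced)
    b = _load_table(expected)
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        raise ValueError(
            f"schema mismatch: {list(a.columns)}x{len(a)} vs {list(b.columns)}x{len(b)}"
        )
    diffs = []
    for col in a.columns:
        tol = 0.0
        name = col.lower()
        if "ratio" in name or name in ("ka", "ks", "identity", "r_sub_indel",
                                       "r_indel_repeat", "r_sub_repeat"):
            tol = ratio_tol
        elif "pct" in name or "%" in name or "percent" in name or "gc" in name:
            tol = pct_tol
        for i, (va, vb) in enumerate(zip(a[col], b[col])):
            if _cells_equal(va, vb, tol):
                continue
            diffs.append({"row": i, "column": col, "produced": va, "expected": vb})
    return pd.DataFrame(diffs, columns=["row", "column", "produced", "expected"])


def _cells_equal(va, vb, tol: float) -> bool:
    if pd.isna(va) and pd.isna(vb):
        return True
    try:
        fa, fb = float(va), float(vb)
    except (TypeError, ValueError):
        return str(va) == str(vb)
    if tol == 0.0:
        return fa == fb
    return abs(fa - fb) <= tol


def _load_table(src) -> pd.DataFrame:
    if isinstance(src, pd.DataFrame):
        return src.reset_index(drop=True)
    return pd.read_csv(src, sep="\t", comment="#")
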