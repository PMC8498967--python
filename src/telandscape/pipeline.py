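"""End-to-end orchestration: abundance -> diversity -> landscape -> TT:I
-> expression, with a consolidated plain-text report.

The pipeline has no hidden state: each stage is exactly the
corresponding library call on the same inputs, so running stages
individually reproduces the bundle.  Stages whose inputs are absent
from the config are skipped with a logged notice.  Every report embeds
the config and seed for provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import abundance as ab
from . import diversity as dv
from . import expression as ex
from . import landscape as ls
from . import structure as st
from .errors import UsageError
from .repeatio import read_records, read_tsv, write_tsv

log = logging.getLogger("telandscape.pipeline")

CONFIG_VERSION = 1


def load_config(path) -> dict:
    config = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return validate_config(config)


def validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise UsageError("config must be a mapping")
    version = config.get("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise UsageError(f"unsupported config version {version!r}")
    if "abundance" in config and "total_bp" not in config["abundance"]:
        raise UsageError("abundance stage requires total_bp (summed read bp)")
    for stage in ("abundance", "tti", "expression", "cluster"):
        section = config.get(stage) or {}
        for key, value in section.items():
            if key.endswith(("records", "alignments", "models", "tpm",
                             "protein_hits", "nucl_hits", "genes", "fasta")):
                if value and not Path(value).exists():
                    raise UsageError(f"{stage}.{key}: no such file {value!r}")
    return config


def load_transcript_records(
    tpm_path, protein_hits_path=None, nucl_hits_path=None, genes_path=None
) -> list[ex.TranscriptRecord]:
    """Assemble transcript records from the tabular evidence tracks.

    ``tpm``: contig_id, tpm.  ``protein_hits``: contig_id, superfamily,
    e_value [, start, end, strand, frame].  ``nucl_hits``: contig_id,
    library_id, aln_len, identity, library_coverage.  ``genes``:
    contig_id, gene_id [, start, end, strand].
    """
    tpm = read_tsv(tpm_path)
    records = {
        str(r.contig_id): ex.TranscriptRecord(str(r.contig_id), float(r.tpm))
        for r in tpm.itertuples()
    }

    def _opt(row, name, cast):
        value = getattr(row, name, None)
        return None if value is None or pd.isna(value) else cast(value)

    if protein_hits_path:
        for r in read_tsv(protein_hits_path).itertuples():
            rec = records.get(str(r.contig_id))
            if rec is not None:
                rec.protein_te_hits.append(
                    ex.ProteinTEHit(
                        superfamily=str(r.superfamily),
                        e_value=float(r.e_value),
                        start=_opt(r, "start", int),
                        end=_opt(r, "end", int),
                        strand=_opt(r, "strand", str),
                        frame=_opt(r, "frame", int),
                    )
                )
    if nucl_hits_path:
        for r in read_tsv(nucl_hits_path).itertuples():
            rec = records.get(str(r.contig_id))
            if rec is not None:
                rec.nucl_te_hits.append(
                    ex.NuclTEHit(
                        library_id=str(r.library_id),
                        aln_len=int(r.aln_len),
                        identity=float(r.identity),
                        library_coverage=float(r.library_coverage),
                    )
                )
    if genes_path:
        for r in read_tsv(genes_path).itertuples():
            rec = records.get(str(r.contig_id))
            if rec is not None:
                rec.gene_annotations.append(
                    ex.GeneAnnotation(
                        gene_id=str(r.gene_id),
                        start=_opt(r, "start", int),
                        end=_opt(r, "end", int),
                        strand=_opt(r, "strand", str),
                    )
                )
    return list(records.values())


def run_characterization(config: dict, output_dir) -> dict:
    """Execute every stage whose inputs are present; write per-stage TSVs
    plus ``summary.txt``.  Returns the in-memory results bundle."""
    config = validate_config(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    level = config.get("level", "superfamily")

    table = None
    if "abundance" in config:
        section = config["abundance"]
        records = read_records(section["records"])
        table = ab.masked_fraction_table(
            records,
            total_bp=int(section["total_bp"]),
            level=level,
            weighting=section.get("weighting", "bp"),
        )
        table.to_tsv(out / "abundance.tsv")
        results["abundance"] = table

        try:
            community = dv.community_proportions(
                table,
                include_unclassified=(config.get("diversity") or {}).get(
                    "include_unclassified", False
                ),
            )
            res = dv.diversity_result(community)
            results["diversity"] = res
            write_tsv(
                pd.DataFrame(
                    [
                        {
                            "level": level,
                            "shannon": res.shannon,
                            "gini_simpson": res.gini_simpson,
                            "richness": res.richness,
                        }
                    ]
                ),
                out / "diversity.tsv",
            )
        except Exception as exc:  # diversity is derived; report and move on
            log.warning("diversity stage skipped: %s", exc)

        section_ls = config.get("landscape") or {}
        divs = ls.best_hit_divergence(records)
        landscapes = ls.build_landscape(
            divs,
            weight=section_ls.get("weight", "reads"),
            bin_width=float(section_ls.get("bin_width", 1.0)),
        )
        calls, counts = ls.activity_summary(
            landscapes,
            abundance=table,
            min_genome_fraction=float(
                section_ls.get("min_genome_fraction", 0.00005)
            ),
        )
        write_tsv(ls.landscape_table(landscapes), out / "landscape.tsv")
        write_tsv(calls, out / "activity.tsv")
        results["activity"] = (calls, counts)

    if "tti" in config:
        section = config["tti"]
        alignments = st.read_alignments(section["alignments"])
        models = st.read_element_models(section["models"])
        sweep = st.tti_sweep(
            alignments,
            models,
            thresholds=tuple(section.get("thresholds", (20, 30, 40, 50))),
        )
        write_tsv(sweep, out / "tti.tsv")
        results["tti"] = sweep

    if "expression" in config:
        section = config["expression"]
        records = load_transcript_records(
            section["tpm"],
            section.get("protein_hits"),
            section.get("nucl_hits"),
            section.get("genes"),
        )
        assignments, counts = ex.categorize_transcripts(
            records, min_tpm=float(section.get("min_tpm", 0.01))
        )
        summary = ex.expression_summary(
            assignments, records,
            denominator=section.get("denominator", "million"),
        )
        results["expression"] = {"counts": counts, "summary": summary}
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "category": c,
                        "n_contigs": counts.get(c, 0),
                        "summed_tpm": summary["category_tpm"][c],
                        "fraction": summary["category_fraction"][c],
                    }
                    for c in ex.CATEGORIES
                ]
            ),
            out / "expression_categories.tsv",
        )
        write_tsv(
            pd.DataFrame(
                summary["superfamily_tpm"].items(),
                columns=["superfamily", "summed_tpm"],
            ),
            out / "expression_superfamilies.tsv",
        )
        if table is not None:
            try:
                r, p, n = ex.abundance_expression_correlation(
                    table, summary["superfamily_tpm"]
                )
                results["expression"]["correlation"] = (r, p, n)
            except Exception as exc:
                log.warning("abundance-expression correlation skipped: %s", exc)

    _write_summary(results, out)
    return results


def _write_summary(results: dict, out: Path) -> None:
    lines = ["# TE landscape characterization summary", ""]
    lines.append("## config")
    lines.append(json.dumps(results["config"], indent=2, default=str))
    if "abundance" in results:
        table = results["abundance"]
        lines += [
            "",
            "## abundance",
            f"surveyed bp: {table.total_bp}",
            f"masked: {table.pct_masked:.2f}%",
        ]
    if "diversity" in results:
        res = results["diversity"]
        lines += [
            "",
            "## diversity",
            f"shannon (nats): {res.shannon:.4f}",
            f"gini_simpson: {res.gini_simpson:.4f}",
            f"richness: {res.richness}",
        ]
    if "activity" in results:
        _, counts = results["activity"]
        lines += [
            "",
            "## activity",
            f"superfamilies assessed: {counts['n_assessed']}",
            f"called active: {counts['n_active']}",
        ]
    if "tti" in results:
        lines += ["", "## TT:I", results["tti"].to_string(index=False)]
    if "expression" in results:
        expr = results["expression"]
        lines += ["", "## expression"]
        for cat, tpm in expr["summary"]["category_tpm"].items():
            frac = expr["summary"]["category_fraction"][cat]
            lines.append(f"{cat}: summed TPM {tpm:.1f} ({100 * frac:.1f}%)")
        if "correlation" in expr:
            r, p, n = expr["correlation"]
            lines.append(
                f"abundance-expression Pearson r = {r:.3f} "
                f"(p = {p:.2e}, n = {n})"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
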