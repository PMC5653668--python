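"""File interfaces: VCF, SNP-count TSV, SEG, BED, newick, YAML config.

Internal coordinates are 0-based half-open; every file interface is 1-based
inclusive (VCF/SEG convention) except BED, which is 0-based half-open by
definition.  Write -> read -> write round-trips are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pysam

from .variants import MUTATION_COLUMNS

SEG_HEADER = ["sample", "chrom", "start", "end", "num_mark", "seg_mean"]


# -- SNP counts --------------------------------------------------------------


def write_snp_counts(df: pd.DataFrame, path: str | Path) -> None:
    """TSV of germline-het SNP read counts: chrom, pos (1-based), sample,
    ref_count, alt_count."""
    df[["chrom", "pos", "sample", "ref_count", "alt_count"]].to_csv(
        path, sep="\t", index=False
    )


def read_snp_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "pos": int, "sample": str,
               "ref_count": int, "alt_count": int},
    )


# -- mutations as VCF --------------------------------------------------------


def write_mutations_vcf(
    table: pd.DataFrame,
    path: str | Path,
    genome: dict[str, int],
    filters: dict[str, str] | None = None,
) -> None:
    """Multi-sample VCF with per-sample AD (ref, alt) and DP FORMAT fields.

    ``filters`` maps mutation_id to a FILTER code for screened-out records;
    unlisted mutations are PASS.
    """
    header = pysam.VariantHeader()
    for chrom, length in genome.items():
        header.contigs.add(chrom, length=length)
    header.filters.add("candidate_fail", None, None,
                       "failed discovery-stringency thresholds")
    header.filters.add("homopolymer", None, None, "inside polyN tract >= 5")
    header.filters.add("low_coverage", None, None,
                       "average distinct coverage below 50x")
    header.filters.add("not_unique", None, None, "failed uniqueness screen")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Distinct read depth")
    header.info.add("MUTID", 1, "String", "Mutation identifier")
    header.info.add("CONTEXT", 1, "String", "Reference context around the variant")
    samples = sorted(table["sample"].unique())
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        wide = table.set_index(["mutation_id", "sample"])
        meta = table.drop_duplicates("mutation_id").sort_values(
            ["chrom", "pos", "mutation_id"], kind="stable"
        )
        for m in meta.itertuples():
            rec = vcf.new_record(
                contig=m.chrom, start=int(m.pos) - 1, alleles=(m.ref, m.alt)
            )
            rec.info["MUTID"] = m.mutation_id
            rec.info["CONTEXT"] = m.context
            code = (filters or {}).get(m.mutation_id)
            rec.filter.add(code if code else "PASS")
            for s in samples:
                row = wide.loc[(m.mutation_id, s)]
                depth = int(row["distinct_coverage"])
                alt = int(row["altered_reads"])
                rec.samples[s]["AD"] = (depth - alt, alt)
                rec.samples[s]["DP"] = depth
            vcf.write(rec)


def read_mutations_vcf(path: str | Path) -> pd.DataFrame:
    """Read a mutation VCF back into the long-form table."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            mut_id = rec.info["MUTID"]
            for s in rec.samples:
                ad = rec.samples[s]["AD"]
                rows.append(
                    {
                        "mutation_id": mut_id,
                        "chrom": rec.contig,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": rec.alts[0],
                        "context": rec.info["CONTEXT"],
                        "sample": s,
                        "distinct_coverage": int(rec.samples[s]["DP"]),
                        "altered_reads": int(ad[1]),
                    }
                )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


# -- segments ----------------------------------------------------------------


def write_seg(segments: pd.DataFrame, sample: str, path: str | Path,
              mean_col: str = "maf_tumor") -> None:
    """SEG file (1-based inclusive): sample, chrom, start, end, num_mark,
    seg_mean."""
    out = pd.DataFrame(
        {
            "sample": sample,
            "chrom": segments["chrom"],
            "start": segments["start"] + 1,
            "end": segments["end"],
            "num_mark": segments.get("n_snps", segments.get("n_bins")),
            "seg_mean": segments[mean_col],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["start"] = df["start"] - 1
    return df


def write_patient_segments(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_patient_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["start"] = df["start"] - 1
    return df


def write_loh_bed(patient_segments: pd.DataFrame, sample: str,
                  path: str | Path) -> None:
    """BED (0-based half-open) of the intervals called LOH in one sample."""
    sel = patient_segments[patient_segments[f"loh_{sample}"]]
    with open(path, "w") as fh:
        for seg in sel.itertuples():
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.marker_id}\n")


# -- misc --------------------------------------------------------------------


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_yaml(obj, path: str | Path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: str | Path):
    import yaml

    return yaml.safe_load(Path(path).read_text())
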