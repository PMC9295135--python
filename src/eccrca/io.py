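"""Tabular and sequence output formats of the pipeline.

The call table is a TSV with one row per RCA read (accepted circles and
rejected reads with their reason); it is the hand-off point between the
caller and the catalog stage, and round-trips through
:func:`read_call_table`.  Consensus sequences go to FASTA, variants to a
small TSV report (1-based positions, as variant reports conventionally
print), accepted circles to BED12 with per-fragment BED6 rows in a
companion file for circles spanning several chromosomes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from eccrca.caller import CircleCall, FragmentLocus
from eccrca.consensus import Variant

__all__ = [
    "write_call_table",
    "read_call_table",
    "write_consensus_fasta",
    "write_variant_table",
    "write_bed",
    "read_chrom_sizes",
]

_CALL_COLUMNS = [
    "read_id",
    "status",
    "reason",
    "n_fragments",
    "full_passes",
    "circle_length",
    "fragments",
    "pass_counts",
]


def write_call_table(calls: Iterable[CircleCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "read_id": c.read_id,
                "status": c.status,
                "reason": c.reason or ".",
                "n_fragments": c.n_fragments,
                "full_passes": c.full_passes,
                "circle_length": c.circle_length,
                "fragments": ";".join(str(f) for f in c.fragments) or ".",
                "pass_counts": ",".join(map(str, c.pass_counts)) or ".",
            }
        )
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_call_table(path: str | Path) -> list[CircleCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls: list[CircleCall] = []
    for row in df.itertuples(index=False):
        fragments = (
            [FragmentLocus.from_string(s) for s in row.fragments.split(";")]
            if row.fragments != "."
            else []
        )
        pass_counts = (
            [int(x) for x in row.pass_counts.split(",")] if row.pass_counts != "." else []
        )
        calls.append(
            CircleCall(
                read_id=row.read_id,
                status=row.status,
                reason=None if row.reason == "." else row.reason,
                fragments=fragments,
                pass_counts=pass_counts,
                full_passes=int(row.full_passes),
            )
        )
    return calls


def write_consensus_fasta(
    entries: Sequence[tuple[CircleCall, str]], path: str | Path
) -> None:
    """FASTA of consensus sequences; headers carry fragments and passes."""
    with open(path, "w") as fh:
        for circle, seq in entries:
            frags = ";".join(str(f) for f in circle.fragments)
            fh.write(
                f">{circle.read_id} fragments={frags} "
                f"full_passes={circle.full_passes} length={len(seq)}\n"
            )
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_variant_table(
    entries: Sequence[tuple[str, Variant]], path: str | Path
) -> None:
    """Variant report TSV: read id, chrom, 1-based pos, ref, alt, depth, af."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tpos\tkind\tref\talt\tdepth\talt_count\taf\n")
        for read_id, v in entries:
            fh.write(
                f"{read_id}\t{v.chrom}\t{v.pos + 1}\t{v.kind}\t{v.ref}\t{v.alt}"
                f"\t{v.depth}\t{v.alt_count}\t{v.af:.4f}\n"
            )


def write_bed(calls: Iterable[CircleCall], bed12_path: str | Path, bed6_path: str | Path) -> None:
    """Accepted circles as BED12 (single-chromosome) plus per-fragment BED6.

    BED12 blocks require one chromosome; circles whose fragments span
    several chromosomes appear only in the BED6 companion.
    """
    bed12: list[str] = []
    bed6: list[str] = []
    for c in calls:
        if not c.accepted:
            continue
        for i, f in enumerate(c.fragments):
            bed6.append(
                f"{f.chrom}\t{f.start}\t{f.end}\t{c.read_id}_f{i}\t{c.full_passes}\t{f.strand}"
            )
        chroms = {f.chrom for f in c.fragments}
        if len(chroms) == 1:
            frags = sorted(c.fragments, key=lambda f: f.start)
            start = frags[0].start
            end = max(f.end for f in frags)
            sizes = ",".join(str(f.length) for f in frags)
            starts = ",".join(str(f.start - start) for f in frags)
            bed12.append(
                f"{frags[0].chrom}\t{start}\t{end}\t{c.read_id}\t{c.full_passes}\t"
                f"{c.fragments[0].strand}\t{start}\t{end}\t0,0,0\t{len(frags)}\t{sizes}\t{starts}"
            )
    Path(bed12_path).write_text("".join(line + "\n" for line in bed12))
    Path(bed6_path).write_text("".join(line + "\n" for line in bed6))


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, size = line.split("\t")[:2]
        sizes[name] = int(size)
    return sizes
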