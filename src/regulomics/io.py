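"""Readers and writers for the plain-text formats the pipeline touches.

BED/BEDPE are tab-separated without headers; tabular inputs and outputs are
TSV with a header row (pandas handles those at call sites). Parsers validate
interval invariants and report the offending line number on failure.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

from .intervals import GenomicInterval, Link, Peak

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed line in a BED-like file; message names the line number."""


def _fields(line: str, lineno: int, minimum: int, path: PathLike) -> List[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < minimum:
        raise ParseError(
            f"{path}:{lineno}: expected ≥{minimum} tab-separated fields, "
            f"got {len(parts)}"
        )
    return parts


def _interval(chrom: str, start: str, end: str, strand: str,
              lineno: int, path: PathLike) -> GenomicInterval:
    try:
        return GenomicInterval(chrom, int(start), int(end), strand)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_bed(
    path: PathLike,
    with_signal: bool = False,
    signal_col: int = 7,
    qvalue_col: Optional[int] = None,
) -> List[Peak]:
    """Read a BED3+ file into peaks, preserving input order.

    ``signal_col`` is the 1-based column holding the signal value
    (narrowPeak's signalValue is column 7). Lines starting with ``#`` or
    ``track`` are skipped.
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _fields(line, lineno, 3, path)
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-." else "."
            iv = _interval(parts[0], parts[1], parts[2], strand, lineno, path)
            signal = 0.0
            if with_signal:
                if len(parts) < signal_col:
                    raise ParseError(
                        f"{path}:{lineno}: signal column {signal_col} missing"
                    )
                signal = float(parts[signal_col - 1])
            qvalue = None
            if qvalue_col is not None and len(parts) >= qvalue_col:
                qvalue = float(parts[qvalue_col - 1])
            peaks.append(Peak(iv, signal=signal, qvalue=qvalue, name=name))
    return peaks


def write_bed(path: PathLike, peaks: Sequence[Peak], with_signal: bool = False) -> None:
    """Write peaks as BED6(+signal); inverse of :func:`read_bed`."""
    with open(path, "w") as fh:
        for p in peaks:
            row = [p.interval.chrom, str(p.interval.start), str(p.interval.end),
                   p.name, "0", p.interval.strand]
            if with_signal:
                row.append(repr(p.signal))
            fh.write("\t".join(row) + "\n")


def read_bedpe(
    path: PathLike,
    ccscore_col: int = 8,
    pvalue_col: Optional[int] = None,
) -> List[Link]:
    """Read a BEDPE file into links with canonically ordered anchors.

    Columns 1-6 are the two anchors; ``ccscore_col``/``pvalue_col`` are
    1-based indices of the contact-count score and p-value columns.
    """
    if ccscore_col < 7:
        raise ValueError("ccscore_col must point past the six coordinate columns")
    links: List[Link] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _fields(line, lineno, 6, path)
            a1 = _interval(parts[0], parts[1], parts[2], ".", lineno, path)
            a2 = _interval(parts[3], parts[4], parts[5], ".", lineno, path)
            name = parts[6] if len(parts) > 6 else "."
            if len(parts) < ccscore_col:
                raise ParseError(
                    f"{path}:{lineno}: CCscore column {ccscore_col} missing"
                )
            ccscore = float(parts[ccscore_col - 1])
            pvalue = 1.0
            if pvalue_col is not None:
                if len(parts) < pvalue_col:
                    raise ParseError(
                        f"{path}:{lineno}: p-value column {pvalue_col} missing"
                    )
                pvalue = float(parts[pvalue_col - 1])
            links.append(Link(a1, a2, ccscore=ccscore, pvalue=pvalue, name=name))
    return links


def write_bedpe(path: PathLike, links: Sequence[Link],
                extra_cols: Optional[Sequence[Sequence]] = None) -> None:
    """Write links as BEDPE: anchors, name, ccscore, pvalue[, extras]."""
    with open(path, "w") as fh:
        for i, lk in enumerate(links):
            row = [lk.anchor1.chrom, str(lk.anchor1.start), str(lk.anchor1.end),
                   lk.anchor2.chrom, str(lk.anchor2.start), str(lk.anchor2.end),
                   lk.name, repr(lk.ccscore), repr(lk.pvalue)]
            if extra_cols is not None:
                row.extend(str(v) for v in extra_cols[i])
            fh.write("\t".join(row) + "\n")


def read_genome_tsv(path: PathLike) -> List[tuple]:
    """Read a (chrom, length) TSV without header."""
    genome = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected chrom<TAB>length")
            genome.append((parts[0], int(parts[1])))
    return genome


def write_run_manifest(path: PathLike, config: dict, seed: int) -> None:
    """Write a JSON manifest of the run: config, seed, library versions."""
    import numpy
    import pandas
    import scipy
    import sklearn

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
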