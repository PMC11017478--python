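"""Readers and writers for the field's plain-text formats.

Supported formats:

* GENEPOP genotype files (2- or 3-digit allele codes, ``POP`` sections,
  comma-terminated individual names) — the exchange format of classic
  microsatellite software.
* TPS landmark files (``LM=``, point rows, ``ID=``, optional ``SCALE=``).
* Degree / decimal-minute GPS coordinate strings such as ``65°34′802″``
  (read as 65° 34.802′).
* PHYLIP square distance matrices.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix

from .containers import LandmarkSet, GenotypeTable

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_tps",
    "write_tps",
    "parse_coordinate",
    "write_phylip_distances",
]


def read_genepop(path) -> GenotypeTable:
    """Read a GENEPOP file into a :class:`GenotypeTable`.

    Populations are named after the last individual of each ``POP`` block's
    first line prefix if a label cannot be derived; by convention we use the
    first individual's name stem shared by the block, falling back to
    ``pop1 .. popK``.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError("empty GENEPOP file")
    header = lines[0]  # title line, ignored
    del header
    # locus names: either one per line, or a single comma-separated line
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend([c.strip() for c in chunk.split(",") if c.strip()])
        i += 1
    if not loci:
        raise ValueError("no locus names before first POP")

    pops, inds, rows = [], [], []
    pop_idx = 0
    current_pop = None
    digits = None
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            current_pop = None
            continue
        if "," not in line:
            raise ValueError(f"malformed individual line (no comma): {line!r}")
        name, geno = line.split(",", 1)
        name = name.strip()
        calls = geno.split()
        if len(calls) != len(loci):
            raise ValueError(
                f"individual {name!r}: {len(calls)} genotypes for {len(loci)} loci"
            )
        if digits is None:
            digits = len(calls[0]) // 2
            if len(calls[0]) not in (4, 6):
                raise ValueError("allele codes must be 2- or 3-digit")
        row = np.zeros((len(loci), 2), dtype=np.int64)
        for l, call in enumerate(calls):
            if len(call) != 2 * digits:
                raise ValueError(f"bad genotype {call!r} for {name!r}")
            row[l, 0] = int(call[:digits])
            row[l, 1] = int(call[digits:])
        if current_pop is None:
            current_pop = f"pop{pop_idx}"
        pops.append(current_pop)
        inds.append(name)
        rows.append(row)
    if not rows:
        raise ValueError("no individuals found")
    return GenotypeTable(np.stack(rows), np.array(pops, dtype=object),
                         np.array(inds, dtype=object), loci)


def write_genepop(gt: GenotypeTable, path, title: str = "cavecharr export",
                  digits: int = 3) -> None:
    """Write a :class:`GenotypeTable` as a GENEPOP file."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if gt.alleles.max(initial=0) >= 10 ** digits:
        raise ValueError("allele code does not fit the requested digit width")
    out = [title]
    out.extend(gt.loci)
    for pop in gt.population_names:
        out.append("POP")
        rows = np.flatnonzero(gt.populations == pop)
        for r in rows:
            calls = "  ".join(
                f"{gt.alleles[r, l, 0]:0{digits}d}{gt.alleles[r, l, 1]:0{digits}d}"
                for l in range(gt.n_loci)
            )
            out.append(f"{gt.individuals[r]} ,  {calls}")
    Path(path).write_text("\n".join(out) + "\n")


def read_tps(path) -> tuple[np.ndarray, list[str], list[float | None]]:
    """Read a TPS file.

    Returns ``(coords, ids, scales)`` where ``coords`` is
    ``(n_specimens, n_landmarks, 2)``.  Coordinates are multiplied by
    ``SCALE=`` when present.  Curve records are not supported.
    """
    text = Path(path).read_text()
    blocks = re.split(r"(?=^LM\s*=)", text, flags=re.MULTILINE)
    configs, ids, scales = [], [], []
    for block in blocks:
        if not block.strip():
            continue
        lines = [ln.strip() for ln in block.strip().splitlines()]
        m = re.match(r"LM\s*=\s*(\d+)", lines[0])
        if not m:
            raise ValueError(f"TPS block does not start with LM=: {lines[0]!r}")
        k = int(m.group(1))
        pts = []
        ident, scale = None, None
        for ln in lines[1:]:
            if ln.upper().startswith("ID"):
                ident = ln.split("=", 1)[1].strip()
            elif ln.upper().startswith("SCALE"):
                scale = float(ln.split("=", 1)[1])
            elif ln.upper().startswith(("IMAGE", "CURVES", "POINTS")):
                continue
            elif ln:
                xy = ln.split()
                if len(xy) != 2:
                    raise ValueError(f"bad landmark row: {ln!r}")
                pts.append([float(xy[0]), float(xy[1])])
        if len(pts) != k:
            raise ValueError(f"LM={k} but {len(pts)} rows found")
        arr = np.asarray(pts, dtype=float)
        if scale is not None:
            arr = arr * scale
        configs.append(arr)
        ids.append(ident if ident is not None else f"spec{len(ids)}")
        scales.append(scale)
    if not configs:
        raise ValueError("no TPS records found")
    ks = {c.shape[0] for c in configs}
    if len(ks) != 1:
        raise ValueError("inconsistent landmark counts across specimens")
    return np.stack(configs), ids, scales


def write_tps(lms: LandmarkSet, path) -> None:
    out = []
    for i in range(lms.n_specimens):
        out.append(f"LM={lms.n_landmarks}")
        for x, y in lms.coords[i]:
            out.append(f"{x:.6f} {y:.6f}")
        out.append(f"ID={lms.specimen_ids[i]}")
    Path(path).write_text("\n".join(out) + "\n")


_COORD_RE = re.compile(
    r"""^\s*(-?\d+(?:\.\d+)?)\s*[°d]\s*        # degrees
        (?:(\d+(?:\.\d+)?)\s*[′'´m]\s*)?       # minutes
        (?:(\d+(?:\.\d+)?)\s*[″"s]\s*)?        # milli-minutes / seconds field
        ([NSEW])?\s*$""",
    re.VERBOSE,
)


def parse_coordinate(text) -> float:
    """Parse a GPS coordinate to decimal degrees.

    Accepts plain decimal degrees or degree / decimal-minute strings in which
    the third field holds thousandths of a minute: ``65°34′802″`` means
    65° 34.802′ = 65.58003°.  A trailing hemisphere letter (S/W negates) is
    honoured.
    """
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        return float(text)
    s = str(text).strip()
    try:
        return float(s)
    except ValueError:
        pass
    m = _COORD_RE.match(s)
    if not m:
        raise ValueError(f"unparseable coordinate: {text!r}")
    deg = float(m.group(1))
    minutes = float(m.group(2)) if m.group(2) else 0.0
    if m.group(3):
        frac = m.group(3)
        minutes += float(frac) / 10 ** len(frac)
    value = abs(deg) + minutes / 60.0
    if deg < 0:
        value = -value
    if m.group(4) in ("S", "W"):
        value = -value
    return value


def write_phylip_distances(dm: DistanceMatrix, path) -> None:
    """Write a square PHYLIP distance matrix (names truncated/padded to 10)."""
    n = dm.shape[0]
    out = [f"{n:5d}"]
    for i, name in enumerate(dm.ids):
        row = " ".join(f"{dm.data[i, j]:.6f}" for j in range(n))
        out.append(f"{str(name)[:10]:<10s} {row}")
    Path(path).write_text("\n".join(out) + "\n")
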