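"""Readers and writers for the pipeline's file formats.

Formats covered: GenePop genotype files (2- or 3-digit allele codes), FASTA
with population labels, ESRI ASCII grids for rasters, GeoJSON for polygons,
CSV for tabular artifacts (Q-matrices, DIC tables, populations, occurrences,
diversity and predictor tables), YAML for configuration and truth records.

GenePop has no population-name field, so the writer encodes the population
in each individual identifier as ``population|individual``; the reader
splits on ``|`` when present and otherwise numbers the blocks ``pop1``,
``pop2``, ...
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .admixture import QMatrix
from .grid import BinaryMap, GridGeometry, Raster
from .popgen import GenotypeTable, SequenceSample
from .refugia import AncestralArea
from .sdm import OccurrenceSet

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_fasta_populations",
    "write_fasta_populations",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geojson_areas",
    "write_geojson_areas",
    "read_qmatrix",
    "write_qmatrix",
    "read_occurrences",
    "write_occurrences",
    "read_yaml",
    "write_yaml",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GenePop


def _split_code(code: str, width: int) -> tuple[float, float]:
    a, b = int(code[:width]), int(code[width:])
    if a == 0 or b == 0:
        return (np.nan, np.nan)
    return (float(a), float(b))


def read_genepop(path) -> GenotypeTable:
    """Parse a GenePop file: title line, locus names, POP-delimited blocks of
    ``ident , 004002 003003 ...`` lines.  ``0000``/``000000`` is missing."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: not a GenePop file (too short)")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        loci.extend(l.strip() for l in lines[i].split(",") if l.strip())
        i += 1
    if not loci:
        raise ParseError(f"{path}: no locus names before the first POP line")
    records = {"population": [], "individual": [], "locus": [], "allele_a": [], "allele_b": []}
    width: int | None = None
    pop_idx = 0
    pop_name = None
    for lineno, line in enumerate(lines[i:], start=i + 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.upper() == "POP":
            pop_idx += 1
            pop_name = None
            continue
        if pop_idx == 0:
            raise ParseError(f"{path}:{lineno}: genotype line before any POP line")
        if "," not in stripped:
            raise ParseError(f"{path}:{lineno}: missing ',' separator")
        ident, geno = stripped.split(",", 1)
        ident = ident.strip()
        if "|" in ident:
            pop, ind = ident.split("|", 1)
        else:
            pop, ind = f"pop{pop_idx}", ident
        if pop_name is None:
            pop_name = pop
        codes = geno.split()
        if len(codes) != len(loci):
            raise ParseError(f"{path}:{lineno}: expected {len(loci)} genotypes, found {len(codes)}")
        for locus, code in zip(loci, codes):
            if len(code) not in (4, 6) or not code.isdigit():
                raise ParseError(f"{path}:{lineno}: malformed genotype code {code!r}")
            w = len(code) // 2
            if width is None:
                width = w
            elif w != width:
                raise ParseError(
                    f"{path}:{lineno}: mixed {2 * width}- and {2 * w}-digit allele codes"
                )
            a, b = _split_code(code, w)
            records["population"].append(pop_name)
            records["individual"].append(ind)
            records["locus"].append(locus)
            records["allele_a"].append(a)
            records["allele_b"].append(b)
    return GenotypeTable(pd.DataFrame(records))


def write_genepop(table: GenotypeTable, path, title: str = "meltingpot genotypes",
                  digits: int = 3) -> None:
    loci = table.loci
    width = digits
    lines = [title]
    lines.extend(str(l) for l in loci)
    for pop in table.populations:
        lines.append("POP")
        sub = table.population(pop)
        for ind, ind_rows in sub.groupby("individual", sort=False):
            by_locus = ind_rows.set_index("locus")
            codes = []
            for locus in loci:
                if locus in by_locus.index and not np.isnan(by_locus.loc[locus, "allele_a"]):
                    a = int(by_locus.loc[locus, "allele_a"])
                    b = int(by_locus.loc[locus, "allele_b"])
                else:
                    a = b = 0
                if a >= 10**width or b >= 10**width:
                    raise ValueError(f"allele code too large for {width}-digit GenePop")
                codes.append(f"{a:0{width}d}{b:0{width}d}")
            lines.append(f"{pop}|{ind} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_populations(path, mapping: dict | None = None) -> list[SequenceSample]:
    """Group aligned FASTA records into per-population samples.

    Population labels come from ``mapping`` (record id -> population) when
    given, else from a ``population|sequence`` record-id convention, else the
    whole file is one population named after the file stem.
    """
    from Bio import SeqIO

    groups: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if mapping is not None:
            pop = mapping.get(rec.id, mapping.get(rec.id.split("|")[0]))
            if pop is None:
                raise ParseError(f"{path}: record {rec.id} has no population in the mapping")
        elif "|" in rec.id:
            pop = rec.id.split("|")[0]
        else:
            pop = Path(path).stem
        groups.setdefault(str(pop), []).append(str(rec.seq))
    if not groups:
        raise ParseError(f"{path}: no FASTA records")
    return [SequenceSample(pop, seqs) for pop, seqs in groups.items()]


def write_fasta_populations(samples: list[SequenceSample], path) -> None:
    with open(path, "w") as fh:
        for sample in samples:
            for i, seq in enumerate(sample.sequences, start=1):
                fh.write(f">{sample.population_id}|{i}\n{seq}\n")


# ---------------------------------------------------------------------------
# ESRI ASCII grids


def read_ascii_grid(path, projected: bool = True, binary: bool = False) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        values = np.loadtxt(fh)
    try:
        rows, cols = int(header["nrows"]), int(header["ncols"])
        cell = header["cellsize"]
    except KeyError as exc:
        raise ParseError(f"{path}: missing ESRI ASCII header field {exc}") from exc
    if "xllcenter" in header:
        x0, y0 = header["xllcenter"], header["yllcenter"]
    else:  # corner registration: shift to the cell centre
        x0 = header.get("xllcorner", 0.0) + cell / 2.0
        y0 = header.get("yllcorner", 0.0) + cell / 2.0
    nodata = header.get("nodata_value", -9999.0)
    values = np.atleast_2d(values)
    if values.shape != (rows, cols):
        raise ParseError(f"{path}: grid shape {values.shape} does not match header")
    geom = GridGeometry(rows, cols, x0, y0, cell, projected=projected)
    cls = BinaryMap if binary else Raster
    return cls(geom, values, nodata=nodata)


def write_ascii_grid(raster: Raster, path) -> None:
    g = raster.geometry
    with open(path, "w") as fh:
        fh.write(
            f"ncols {g.cols}\nnrows {g.rows}\n"
            f"xllcenter {g.x_origin:.6f}\nyllcenter {g.y_origin:.6f}\n"
            f"cellsize {g.cell_size:.6f}\nNODATA_value {raster.nodata:.6f}\n"
        )
        np.savetxt(fh, raster.values, fmt="%.6g")


# ---------------------------------------------------------------------------
# GeoJSON


def read_geojson_areas(path) -> dict[str, AncestralArea]:
    data = json.loads(Path(path).read_text())
    features = data["features"] if data.get("type") == "FeatureCollection" else [data]
    out = {}
    for feat in features:
        props = feat.get("properties") or {}
        name = str(props.get("lineage", f"area{len(out) + 1}"))
        out[name] = AncestralArea(
            shape(feat["geometry"]), lineage=name, hpd_level=float(props.get("hpd_level", 0.7))
        )
    return out


def write_geojson_areas(areas: dict[str, AncestralArea], path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"lineage": area.lineage or name, "hpd_level": area.hpd_level},
            "geometry": mapping(area.polygon),
        }
        for name, area in areas.items()
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


# ---------------------------------------------------------------------------
# CSV / YAML helpers


def read_qmatrix(path) -> QMatrix:
    return QMatrix(pd.read_csv(path))


def write_qmatrix(q: QMatrix, path) -> None:
    q.df.to_csv(path, index=False)


def read_occurrences(path, projected: bool = False) -> OccurrenceSet:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "lon" in cols and "lat" in cols:
        df = df.rename(columns={cols["lon"]: "x", cols["lat"]: "y"})
        projected = False
    return OccurrenceSet(df, projected=projected)


def write_occurrences(occ: OccurrenceSet, path) -> None:
    df = occ.points.copy()
    if not occ.projected:
        df = df.rename(columns={"x": "lon", "y": "lat"})
    df.to_csv(path, index=False)


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
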