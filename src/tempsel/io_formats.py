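"""Reading and writing the formats the pipeline touches.

Genotypes travel as Genepop files (the de facto interchange format of the
field's desktop tools) and as tidy CSV.  Genepop stores alleles as 2- or
3-digit numeric codes, so string-labelled candidate alleles are mapped
through an allele dictionary written as a sidecar CSV next to the Genepop
file; microsatellite repeat numbers are used directly as their own codes.
``000``/``00`` is the missing-data sentinel.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

import pandas as pd

from .datatypes import MICROSATELLITE, GenotypeSample, Locus


class FormatError(ValueError):
    """Parse error; carries the offending line number where applicable."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


_ID_RE = re.compile(r"^(?P<site>.+)-(?P<year>\d+)-\d+$")


def _sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".alleles.csv")


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------


def write_genepop(samples, path, allele_dictionary=None) -> dict:
    """Write *samples* as one Genepop file, one POP block per site x year.

    Returns the allele dictionary used, ``{locus: {allele: code}}``, and
    writes it as a sidecar CSV (``<path>.alleles.csv``) recording locus
    kind, code and label so that :func:`read_genepop` can restore string
    alleles and locus kinds exactly.  At most 999 distinct alleles per
    locus are representable.
    """
    samples = list(samples)
    if not samples:
        raise FormatError("no samples to write")
    loci = samples[0].loci
    for s in samples:
        if s.loci != loci:
            raise FormatError(f"sample {s.site}/{s.year} has a different locus list")
    if allele_dictionary is None:
        allele_dictionary = {}
        for li, loc in enumerate(loci):
            alleles = sorted(
                {
                    a
                    for s in samples
                    for g in (row[li] for row in s.genotypes)
                    if g is not None
                    for a in g
                },
                key=repr,
            )
            if loc.kind == MICROSATELLITE and all(
                isinstance(a, int) and 1 <= a <= 999 for a in alleles
            ):
                codes = {a: int(a) for a in alleles}
            else:
                codes = {a: i + 1 for i, a in enumerate(alleles)}
            if any(c > 999 for c in codes.values()):
                raise FormatError(f"locus {loc.name}: more than 999 distinct alleles")
            allele_dictionary[loc.name] = codes
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("tempsel genotype export\n")
        for loc in loci:
            fh.write(f"{loc.name}\n")
        for s in samples:
            fh.write("POP\n")
            for i, row in enumerate(s.genotypes):
                codes = []
                for li, loc in enumerate(loci):
                    g = row[li]
                    if g is None:
                        codes.append("000000")
                    else:
                        c1 = allele_dictionary[loc.name][g[0]]
                        c2 = allele_dictionary[loc.name][g[1]]
                        codes.append(f"{c1:03d}{c2:03d}")
                fh.write(f"{s.site}-{s.year}-{i + 1:03d} , " + " ".join(codes) + "\n")
    with _sidecar_path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["locus", "kind", "code", "allele"])
        for loc in loci:
            for allele, code in sorted(
                allele_dictionary[loc.name].items(), key=lambda kv: kv[1]
            ):
                writer.writerow([loc.name, loc.kind, code, allele])
    return allele_dictionary


def read_genepop(path, allele_dictionary_path=None) -> list[GenotypeSample]:
    """Parse a Genepop file into one :class:`GenotypeSample` per POP block.

    Accepts 2- or 3-digit diploid codes; ``00``/``000`` decodes to missing.
    If an allele-dictionary sidecar exists (or is given), codes are mapped
    back to their labels and locus kinds restored; otherwise alleles are the
    integer codes themselves and every locus is treated as a microsatellite.
    Individual ids of the form ``site-year-n`` recover site and year; other
    ids fall back to ``pop<k>`` / sequential years.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise FormatError("not a Genepop file: fewer than 3 lines")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = [p.strip() for p in lines[i].split(",") if p.strip()]
        if not chunk:
            raise FormatError("empty locus line", line=i + 1)
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise FormatError("no POP separator found")
    if not locus_names:
        raise FormatError("no locus names before first POP")

    sidecar = Path(allele_dictionary_path) if allele_dictionary_path else _sidecar_path(path)
    decode: dict[str, dict[int, object]] = {}
    kinds: dict[str, str] = {}
    if sidecar.exists():
        with sidecar.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                locus = row["locus"]
                kinds[locus] = row["kind"]
                allele = row["allele"]
                if row["kind"] == MICROSATELLITE:
                    allele = int(allele)
                decode.setdefault(locus, {})[int(row["code"])] = allele
    loci = [Locus(nm, kinds.get(nm, MICROSATELLITE)) for nm in locus_names]

    samples: list[GenotypeSample] = []
    block_rows: list[tuple[int, str, str]] = []  # (line_no, id, codes)

    def flush(block_index: int) -> None:
        if not block_rows:
            raise FormatError("empty POP block", line=i + 1)
        genotypes = []
        site, year = None, None
        for line_no, ind_id, rest in block_rows:
            fields = rest.split()
            if len(fields) != len(locus_names):
                raise FormatError(
                    f"individual {ind_id!r} has {len(fields)} loci, "
                    f"expected {len(locus_names)}",
                    line=line_no,
                )
            row = []
            for locus, code in zip(locus_names, fields):
                if not code.isdigit() or len(code) not in (4, 6):
                    raise FormatError(
                        f"non-numeric or mis-sized genotype code {code!r}",
                        line=line_no,
                    )
                half = len(code) // 2
                c1, c2 = int(code[:half]), int(code[half:])
                if c1 == 0 or c2 == 0:
                    row.append(None)
                    continue
                table = decode.get(locus)
                if table is not None:
                    try:
                        row.append((table[c1], table[c2]))
                    except KeyError as exc:
                        raise FormatError(
                            f"code {exc.args[0]} missing from allele dictionary "
                            f"for locus {locus}",
                            line=line_no,
                        ) from None
                else:
                    row.append((c1, c2))
            genotypes.append(row)
            if site is None:
                m = _ID_RE.match(ind_id)
                if m:
                    site, year = m.group("site"), int(m.group("year"))
        if site is None:
            site, year = f"pop{block_index}", block_index
        samples.append(
            GenotypeSample(site=site, year=year, loci=list(loci), genotypes=genotypes)
        )

    block = -1
    for j in range(i, len(lines)):
        text = lines[j].strip()
        if not text:
            continue
        if text.upper() == "POP":
            if block >= 0:
                flush(block)
                block_rows.clear()
            block += 1
            continue
        if "," not in text:
            raise FormatError("individual line lacks the id/genotype comma", line=j + 1)
        ind_id, rest = text.split(",", 1)
        block_rows.append((j + 1, ind_id.strip(), rest.strip()))
    flush(block)
    return samples


# ---------------------------------------------------------------------------
# tidy CSV genotypes
# ---------------------------------------------------------------------------


def write_genotype_csv(samples, path) -> None:
    """Tidy long-format export: one row per individual x locus."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual", "site", "year", "locus", "kind", "allele1", "allele2"])
        for s in samples:
            for i, row in enumerate(s.genotypes):
                ind = f"{s.site}-{s.year}-{i + 1:03d}"
                for loc, g in zip(s.loci, row):
                    a1, a2 = ("", "") if g is None else (g[0], g[1])
                    writer.writerow([ind, s.site, s.year, loc.name, loc.kind, a1, a2])


def read_genotype_csv(path) -> list[GenotypeSample]:
    """Inverse of :func:`write_genotype_csv`."""
    df = _read_table(path, {"individual", "site", "year", "locus", "allele1", "allele2"})
    if "kind" not in df.columns:
        df["kind"] = MICROSATELLITE
    samples = []
    for (site, year), grp in df.groupby(["site", "year"], sort=False):
        loci = []
        seen = set()
        for _, row in grp.iterrows():
            if row["locus"] not in seen:
                seen.add(row["locus"])
                loci.append(Locus(row["locus"], row["kind"]))
        ind_order = list(dict.fromkeys(grp["individual"]))
        genotypes = []
        for ind in ind_order:
            sub = grp[grp["individual"] == ind].set_index("locus")
            row_g = []
            for loc in loci:
                a1, a2 = sub.loc[loc.name, "allele1"], sub.loc[loc.name, "allele2"]
                if pd.isna(a1) or a1 == "" or pd.isna(a2) or a2 == "":
                    row_g.append(None)
                else:
                    if loc.kind == MICROSATELLITE:
                        a1, a2 = int(a1), int(a2)
                    row_g.append((a1, a2))
            genotypes.append(row_g)
        samples.append(
            GenotypeSample(site=str(site), year=int(year), loci=loci, genotypes=genotypes)
        )
    return samples


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------


def _read_table(path, required: set) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site": str} if "site" in required else None)
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{Path(path).name}: missing required columns {sorted(missing)}"
        )
    return df


def read_expression_table(path) -> pd.DataFrame:
    """CSV with individual, site, epoch, mapped_reads, total_reads columns."""
    df = _read_table(path, {"site", "epoch", "mapped_reads", "total_reads"})
    return df


def read_water_table(path) -> pd.DataFrame:
    """CSV with site, year, epoch label columns plus numeric variables."""
    return _read_table(path, {"site", "year", "epoch"})
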