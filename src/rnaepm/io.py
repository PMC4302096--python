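"""File formats: FASTA input, EPM tables, anchor-constraint export, config.

The anchor writer emits LocARNA-style extended FASTA: each sequence is
followed by ``#A1..#Aw`` annotation rows whose columns, read top to
bottom, spell a fixed-width digit name per anchored column; equal names
across the two sequences mark matched positions of the best chain.
"""

from __future__ import annotations

from Bio import SeqIO

import yaml

from .chaining import Chain
from .epm import Epm
from .params import Params
from .sequence import ALPHABET, InputError, RnaSequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_epm_table",
    "read_epm_table",
    "write_anchor_constraints",
    "parse_anchor_constraints",
    "load_config",
]

EPM_TABLE_VERSION = "1"


def read_fasta(path) -> list:
    """Read all records; T maps to U, lowercase accepted."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    if not records:
        raise InputError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        raw = str(rec.seq)
        bad = set(raw.upper().replace("T", "U")) - ALPHABET
        if bad:
            raise InputError(
                f"record {rec.id!r}: non-nucleotide characters {sorted(bad)}"
                f" (line {_find_line(path, raw)})"
            )
        out.append(RnaSequence(rec.id, raw))
    return out


def _find_line(path, fragment: str) -> int:
    """Best-effort line number of the offending sequence data."""
    probe = fragment[:30]
    try:
        with open(path) as fh:
            for no, line in enumerate(fh, 1):
                if probe and probe in line.strip():
                    return no
    except OSError:
        pass
    return 0


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# EPM tables


def _motif_string(epm: Epm, side: int) -> str:
    """Dot-bracket-with-dots over the EPM's matched positions (sorted)."""
    if side == 0:
        pos = sorted(epm.positions_a())
        opens = {i for (i, _, _, _) in epm.S}
        closes = {j for (_, j, _, _) in epm.S}
    else:
        pos = sorted(epm.positions_b())
        opens = {k for (_, _, k, _) in epm.S}
        closes = {l for (_, _, _, l) in epm.S}
    return "".join(
        "(" if p in opens else ")" if p in closes else "." for p in pos
    )


def write_epm_table(epms, path, params: Params | None = None) -> None:
    """TSV with one row per EPM; reconstructible by `read_epm_table`."""
    with open(path, "w") as fh:
        fh.write(f"#epm_table_version\t{EPM_TABLE_VERSION}\n")
        if params is not None:
            fh.write(
                "#params\tmode={} theta=({},{},{}) alpha=({},{},{}) str_mm={}\n".format(
                    params.mode,
                    params.theta1,
                    params.theta2,
                    params.theta3,
                    params.alpha1,
                    params.alpha2,
                    params.alpha3,
                    params.str_mm,
                )
            )
        fh.write(
            "epm_id\tmode\tscore\tn_matches\tn_pairs\tmatches\tpairs"
            "\tmotif_a\tmotif_b\n"
        )
        for t, e in enumerate(epms, 1):
            matches = ";".join(f"{i}:{k}" for (i, k) in sorted(e.M))
            pairs = ";".join(
                f"{i},{j}:{k},{l}" for (i, j, k, l) in sorted(e.S)
            )
            fh.write(
                f"{t}\t{e.mode}\t{e.score!r}\t{len(e.M)}\t{len(e.S)}\t"
                f"{matches}\t{pairs}\t{_motif_string(e, 0)}\t{_motif_string(e, 1)}\n"
            )


def read_epm_table(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("epm_id\t"):
                continue
            cols = line.split("\t")
            _, mode, score, _, _, matches, pairs = cols[:7]
            M = frozenset(
                tuple(int(v) for v in mm.split(":"))
                for mm in matches.split(";")
                if mm
            )
            S = frozenset()
            if pairs:
                S = frozenset(
                    (
                        int(pp.split(":")[0].split(",")[0]),
                        int(pp.split(":")[0].split(",")[1]),
                        int(pp.split(":")[1].split(",")[0]),
                        int(pp.split(":")[1].split(",")[1]),
                    )
                    for pp in pairs.split(";")
                )
            out.append(Epm(M=M, S=S, mode=mode, score=float(score)))
    return out


# ---------------------------------------------------------------------------
# anchor constraints


def write_anchor_constraints(chain: Chain, seqs, path) -> None:
    """Extended FASTA with #A1..#Aw anchor-name rows per sequence."""
    seqA, seqB = seqs
    matches = sorted(chain.matches)
    for (i, k) in matches:
        if i > len(seqA) or k > len(seqB):
            raise InputError(f"anchor {i}~{k} beyond sequence length")
    width = max(1, len(str(len(matches))))
    names = [str(t + 1).rjust(width, "0") for t in range(len(matches))]
    rows = {}
    for side, seq in ((0, seqA), (1, seqB)):
        grid = [["."] * len(seq) for _ in range(width)]
        for name, mt in zip(names, matches):
            col = mt[side] - 1
            for r in range(width):
                grid[r][col] = name[r]
        rows[side] = ["".join(g) for g in grid]
    with open(path, "w") as fh:
        for side, seq in ((0, seqA), (1, seqB)):
            fh.write(f">{seq.id}\n{seq.residues}\n")
            for r in range(width):
                fh.write(f"#A{r + 1} {rows[side][r]}\n")


def parse_anchor_constraints(path) -> frozenset:
    """Recover the matched position pairs from an anchor file."""
    seqs = []  # list of (id, residues, [rows])
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                seqs.append([line[1:], None, []])
            elif line.startswith("#A"):
                seqs[-1][2].append(line.split(" ", 1)[1])
            else:
                seqs[-1][1] = line
    if len(seqs) != 2:
        raise InputError("anchor file must hold exactly two sequences")
    name_pos = []
    for (_, residues, rows) in seqs:
        here = {}
        for col in range(len(residues)):
            name = "".join(row[col] for row in rows)
            if name.strip("."):
                here[name] = col + 1
        name_pos.append(here)
    common = set(name_pos[0]) & set(name_pos[1])
    return frozenset((name_pos[0][n], name_pos[1][n]) for n in common)


def load_config(path) -> dict:
    """YAML-like key: value configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError("config must be a mapping of option: value")
    return data
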