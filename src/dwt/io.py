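"""File formats: FASTA sequences and PSWM / DWT flat files.

The DWT flat file is whitespace-delimited text: a header line
``#DWT length=<l> lambda=<lam> name=<id>`` followed by one line per
``(i, j, a, b)`` with ``i < j`` (1-based positions):

    i  j  A  C  12.5

PSWM files carry a ``#PSWM length=<l> lambda=<lam>`` header and l rows of
4 counts in A C G T order.  Counts round-trip bit-stably through 12
significant decimal digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO

from .counts import ALPHABET, CountProfile, PairCountTensor, PriorSpec
from .models import AdjModel, DwtModel, PswmModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pswm",
    "write_pswm",
    "read_dwt",
    "write_dwt",
    "read_model",
]

_LETTER_INDEX = {c: i for i, c in enumerate(ALPHABET)}


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; uppercased; only A, C, G, T, N permitted."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        bad = set(seq) - set(ALPHABET + "N")
        if bad:
            raise ValueError(
                f"record {rec.id!r} in {path} contains invalid "
                f"character(s) {sorted(bad)}"
            )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 70):
                fh.write(seq[k:k + 70] + "\n")


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _parse_header(line: str, tag: str) -> dict:
    if not line.startswith(f"#{tag}"):
        raise ValueError(f"expected a #{tag} header, got {line!r}")
    fields = {}
    for tok in line[len(tag) + 1:].split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            fields[k] = v
    return fields


def write_pswm(path, model: PswmModel, name: str = "pswm") -> None:
    lines = [f"#PSWM length={model.length} "
             f"lambda={_fmt(model.prior.lambda_mono)} name={name}"]
    for row in model.profile.counts:
        lines.append(" ".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pswm(path) -> PswmModel:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    fields = _parse_header(lines[0], "PSWM")
    lam = float(fields.get("lambda", 0.5))
    rows = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            continue
        vals = [float(v) for v in ln.split()]
        if len(vals) != 4:
            raise ValueError(f"PSWM row must have 4 counts, got {ln!r}")
        rows.append(vals)
    counts = np.asarray(rows)
    if "length" in fields and int(fields["length"]) != len(rows):
        raise ValueError(
            f"PSWM header length {fields['length']} != {len(rows)} rows")
    if (counts < 0).any():
        raise ValueError("negative counts in PSWM file")
    return PswmModel(CountProfile(counts), PriorSpec(lam))


def write_dwt(path, model, name: str | None = None) -> None:
    """Write a DWT (or ADJ) model's pair counts as the flat-file format."""
    l = model.length
    name = name or getattr(model, "name", "dwt")
    lines = [f"#DWT length={l} lambda={_fmt(model.prior.lambda_mono)} "
             f"name={name}"]
    t = model.pairs.tensor
    for i in range(l):
        for j in range(i + 1, l):
            for a in range(4):
                for b in range(4):
                    lines.append(
                        f"{i + 1} {j + 1} {ALPHABET[a]} {ALPHABET[b]} "
                        f"{_fmt(t[i, j, a, b])}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def read_dwt(path, kind: str = "dwt"):
    """Load a DWT flat file; validates marginal consistency on read.

    ``kind='adj'`` returns an AdjModel over the same pair counts.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    fields = _parse_header(lines[0], "DWT")
    lam = float(fields.get("lambda", 0.5))
    l = int(fields["length"])
    tensor = np.zeros((l, l, 4, 4))
    seen = np.zeros((l, l), dtype=bool)
    for ln in lines[1:]:
        if ln.startswith("#"):
            continue
        toks = ln.split()
        if len(toks) != 5:
            raise ValueError(f"malformed DWT line {ln!r}")
        i, j = int(toks[0]) - 1, int(toks[1]) - 1
        if not (0 <= i < j < l):
            raise ValueError(f"positions out of order/range in line {ln!r}")
        a, b = _LETTER_INDEX[toks[2]], _LETTER_INDEX[toks[3]]
        v = float(toks[4])
        if v < 0:
            raise ValueError(f"negative count in line {ln!r}")
        tensor[i, j, a, b] = v
        tensor[j, i, b, a] = v
        seen[i, j] = True
    missing = [(i + 1, j + 1) for i in range(l) for j in range(i + 1, l)
               if not seen[i, j]]
    if missing:
        raise ValueError(f"DWT file missing pair blocks for positions "
                         f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    pairs = PairCountTensor(tensor)
    try:
        pairs.validate(rtol=1e-6)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    prior = PriorSpec(lam)
    name = fields.get("name", "dwt")
    if kind == "adj":
        return AdjModel(pairs, prior)
    return DwtModel(pairs, prior, name=name)


def read_model(path, kind: str | None = None):
    """Dispatch on the header: #PSWM or #DWT."""
    first = Path(path).read_text().lstrip().splitlines()[0]
    if first.startswith("#PSWM"):
        return read_pswm(path)
    if first.startswith("#DWT"):
        return read_dwt(path, kind=kind or "dwt")
    raise ValueError(f"{path}: unrecognized model file header {first!r}")
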