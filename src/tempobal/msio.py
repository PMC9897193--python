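"""Reading and writing serial haplotype samples in an ms-style text dialect.

Each replicate is a standard ms block (``//``, ``segsites:``, ``positions:``
as fractions of the locus with 6-decimal precision, one 0/1 string per
haplotype) preceded by ``#`` comment lines carrying what vanilla ms has no
slot for: the sampling-block boundaries (age in years and row count, oldest
first — rows appear in that order), the class label, the locus length, the
focal-site column and the provenance (seed, conditioning attempts). A plain
ms parser that skips comments still reads the haplotypes.

A companion metadata table (TSV: replicate_id, block_index, age_years,
n_haplotypes, label, seed, attempts) indexes the file; on reading, row counts
are cross-checked against it when it is supplied.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .simulate import TemporalSample

__all__ = ["write_ms_like", "read_ms_like", "METADATA_COLUMNS"]

METADATA_COLUMNS = [
    "replicate_id",
    "block_index",
    "age_years",
    "n_haplotypes",
    "label",
    "seed",
    "attempts",
]

_POS_DECIMALS = 6


def _seed_str(provenance: dict) -> str:
    seed = provenance.get("seed")
    return json.dumps(seed, separators=(",", ":")) if seed is not None else "null"


def write_ms_like(
    samples: Sequence[TemporalSample],
    path,
    metadata_path: Optional[object] = None,
) -> pd.DataFrame:
    """Write replicates to ``path`` and return the metadata table (also
    written to ``metadata_path`` when given)."""
    path = Path(path)
    meta_rows = []
    with path.open("w") as fh:
        fh.write(f"tempobal-ms {len(samples)}\n")
        for rid, sample in enumerate(samples):
            fh.write("//\n")
            blocks_desc = ";".join(
                f"{age:g}:{M.shape[0]}" for age, M in sample.blocks
            )
            fh.write(f"# blocks: {blocks_desc}\n")
            fh.write(f"# label: {sample.label}\n")
            fh.write(f"# locus_length: {sample.locus_length:g}\n")
            focal = sample.focal_site_index
            fh.write(f"# focal_index: {focal if focal is not None else -1}\n")
            fh.write(f"# seed: {_seed_str(sample.provenance)}\n")
            fh.write(f"# attempts: {sample.provenance.get('attempts', 1)}\n")
            fh.write(f"segsites: {sample.n_sites}\n")
            fracs = sample.positions / sample.locus_length
            fh.write(
                "positions: "
                + " ".join(f"{f:.{_POS_DECIMALS}f}" for f in fracs)
                + "\n"
            )
            for bi, (age, M) in enumerate(sample.blocks):
                for row in M:
                    fh.write("".join("1" if v else "0" for v in row) + "\n")
                meta_rows.append(
                    {
                        "replicate_id": rid,
                        "block_index": bi,
                        "age_years": age,
                        "n_haplotypes": M.shape[0],
                        "label": sample.label,
                        "seed": _seed_str(sample.provenance),
                        "attempts": sample.provenance.get("attempts", 1),
                    }
                )
    meta = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    if metadata_path is not None:
        meta.to_csv(metadata_path, sep="\t", index=False)
    return meta


def _parse_header(lines: list[str], rid: int) -> dict:
    header = {}
    for ln in lines:
        body = ln[1:].strip()
        key, _, value = body.partition(":")
        header[key.strip()] = value.strip()
    if "blocks" not in header:
        raise FormatError(f"replicate {rid}: missing '# blocks:' header")
    try:
        blocks = [
            (float(a), int(n))
            for a, n in (part.split(":") for part in header["blocks"].split(";"))
        ]
    except ValueError as exc:
        raise FormatError(f"replicate {rid}: malformed blocks header") from exc
    header["blocks"] = blocks
    return header


def read_ms_like(
    path, metadata_path: Optional[object] = None
) -> list[TemporalSample]:
    """Parse the dialect back into :class:`TemporalSample` objects.

    ``write_ms_like`` then ``read_ms_like`` is the identity on haplotypes;
    positions are recovered at the 6-decimal precision of the positions line.
    """
    path = Path(path)
    meta = (
        pd.read_csv(metadata_path, sep="\t") if metadata_path is not None else None
    )
    lines = path.read_text().splitlines()
    starts = [i for i, ln in enumerate(lines) if ln.strip() == "//"]
    if not starts:
        raise FormatError(f"{path}: no '//' replicate separators found")
    samples: list[TemporalSample] = []
    bounds = starts + [len(lines)]
    for rid, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
        chunk = [ln for ln in lines[lo + 1 : hi] if ln.strip()]
        header = _parse_header([ln for ln in chunk if ln.startswith("#")], rid)
        body = [ln for ln in chunk if not ln.startswith("#")]
        if len(body) < 2 or not body[0].startswith("segsites:"):
            raise FormatError(f"replicate {rid}: missing segsites line")
        try:
            segsites = int(body[0].split(":", 1)[1])
        except ValueError as exc:
            raise FormatError(f"replicate {rid}: malformed segsites line") from exc
        if not body[1].startswith("positions:"):
            raise FormatError(f"replicate {rid}: missing positions line")
        pos_fields = body[1].split(":", 1)[1].split()
        if len(pos_fields) != segsites:
            raise FormatError(
                f"replicate {rid}: positions count {len(pos_fields)} != "
                f"segsites {segsites}"
            )
        locus_length = float(header.get("locus_length", 1.0))
        positions = np.array([float(f) for f in pos_fields]) * locus_length

        rows = body[2:]
        blocks_spec = header["blocks"]
        expected_rows = sum(n for _, n in blocks_spec)
        if len(rows) != expected_rows:
            raise FormatError(
                f"replicate {rid}: truncated or padded block — expected "
                f"{expected_rows} haplotype rows, found {len(rows)}"
            )
        blocks = []
        cursor = 0
        for age, n in blocks_spec:
            M = np.zeros((n, segsites), dtype=np.uint8)
            for r in range(n):
                line = rows[cursor + r]
                if len(line) != segsites or set(line) - {"0", "1"}:
                    raise FormatError(
                        f"replicate {rid}: haplotype row {cursor + r} is not a "
                        f"{segsites}-character 0/1 string"
                    )
                M[r] = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            cursor += n
            blocks.append((age, M))

        focal = int(header.get("focal_index", -1))
        provenance = {"attempts": int(header.get("attempts", 1))}
        seed_raw = header.get("seed", "null")
        try:
            provenance["seed"] = json.loads(seed_raw)
        except json.JSONDecodeError:
            provenance["seed"] = seed_raw
        sample = TemporalSample(
            blocks=blocks,
            positions=positions,
            focal_site_index=focal if focal >= 0 else None,
            label=header.get("label", "N"),
            locus_length=locus_length,
            provenance=provenance,
        )
        samples.append(sample)

        if meta is not None:
            sub = meta[meta["replicate_id"] == rid]
            if len(sub) != len(blocks):
                raise FormatError(
                    f"replicate {rid}: metadata lists {len(sub)} blocks, file "
                    f"has {len(blocks)}"
                )
            for (_, row), (age, M) in zip(sub.iterrows(), blocks):
                if int(row["n_haplotypes"]) != M.shape[0]:
                    raise FormatError(
                        f"replicate {rid}: row-count mismatch vs metadata at "
                        f"age {age}"
                    )
    return samples
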