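"""Text PED/MAP input and output for genotype panels.

Alleles are written as A (first allele) and B (second allele); the dosage is
the count of B.  Missing genotypes follow the PED convention "0 0".  A panel
tag sidecar TSV (columns ``snp_id``, ``panels``) preserves the nested marker
array membership, which PED/MAP cannot carry.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .population import GenotypePanel, SnpRecord

__all__ = ["read_plink", "write_plink", "read_panel_tags", "write_panel_tags"]

_ALLELES = {0.0: ("A", "A"), 1.0: ("A", "B"), 2.0: ("B", "B")}


def write_plink(panel: GenotypePanel, prefix: str) -> None:
    """Write ``prefix.ped``, ``prefix.map`` and ``prefix.panels.tsv``."""
    with open(prefix + ".map", "w") as fh:
        for s in panel.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
    with open(prefix + ".ped", "w") as fh:
        for i, aid in enumerate(panel.animal_ids):
            sire = panel.sire_of.get(aid, "0")
            fields = ["FAM", aid, sire, "0", "0", "-9"]
            for d in panel.dosages[i]:
                a, b = _ALLELES.get(d, ("0", "0")) if np.isfinite(d) else ("0", "0")
                fields.extend([a, b])
            fh.write(" ".join(fields) + "\n")
    write_panel_tags(panel, prefix + ".panels.tsv")


def write_panel_tags(panel: GenotypePanel, path: str) -> None:
    pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "panels": [",".join(sorted(s.panel_tags)) for s in panel.snps],
        }
    ).to_csv(path, sep="\t", index=False)


def read_panel_tags(path: str) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        row.snp_id: frozenset(row.panels.split(",")) for row in df.itertuples(index=False)
    }


def _parse_map(path: str):
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
            try:
                records.append((int(parts[0]), parts[1], int(parts[3])))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed MAP line") from None
    return records


def read_plink(prefix: str) -> GenotypePanel:
    """Read ``prefix.ped`` + ``prefix.map`` (and panel sidecar if present).

    Per SNP, the alphabetically first allele letter becomes the first allele;
    the dosage counts the other (second) allele.  A file written by
    :func:`write_plink` (alleles A and B) therefore round-trips exactly.
    """
    map_records = _parse_map(prefix + ".map")
    m = len(map_records)
    animal_ids, sires, rows = [], [], []
    allele_codes: list[dict] = [{} for _ in range(m)]
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            animal_ids.append(parts[1])
            sires.append(parts[2])
            geno = np.full(m, np.nan)
            for j in range(m):
                a, b = parts[6 + 2 * j], parts[7 + 2 * j]
                if a == "0" or b == "0":
                    continue
                codes = allele_codes[j]
                for al in sorted({a, b}):
                    if al not in codes:
                        if len(codes) == 2:
                            raise ValueError(
                                f"{prefix}.ped:{lineno}: SNP {map_records[j][1]} "
                                f"has more than two alleles"
                            )
                        codes[al] = len(codes)
                geno[j] = codes[a] + codes[b]
            rows.append(geno)
    dosages = np.vstack(rows) if rows else np.empty((0, m))
    # canonicalize: code 1 must be the alphabetically second allele, not the
    # second allele encountered; flip columns parsed in the other orientation
    for j, codes in enumerate(allele_codes):
        if len(codes) == 2:
            first_seen = min(codes, key=codes.get)
            if first_seen != min(codes):
                dosages[:, j] = 2.0 - dosages[:, j]
    tag_path = prefix + ".panels.tsv"
    tags = read_panel_tags(tag_path) if os.path.exists(tag_path) else {}
    n = max(len(animal_ids), 1)
    snps = []
    for j, (chrom, snp_id, pos) in enumerate(map_records):
        obs = dosages[:, j][np.isfinite(dosages[:, j])]
        p = float(obs.mean() / 2) if obs.size else 0.5
        maf = min(p, 1 - p)
        snps.append(
            SnpRecord(
                snp_id=snp_id,
                chrom=chrom,
                pos=pos,
                target_freq=max(maf, 0.5 / (2 * n)),
                panel_tags=tags.get(snp_id, frozenset({"dense"})),
            )
        )
    sire_of = {a: s for a, s in zip(animal_ids, sires) if s != "0"}
    return GenotypePanel(animal_ids, snps, dosages, sire_of)
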