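"""Reading and writing SFS tables and tallying spectra from VCF.

The SFS TSV format is two columns ``i<TAB>count`` preceded by a single header
line ``#n=<n> folded=<0|1> L=<L>``; the writer/reader round-trips exactly
(counts are written with full repr precision).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectrum import SpectrumCounts, class_sizes

__all__ = ["read_sfs", "write_sfs", "vcf_to_sfs", "VcfTally"]

_HEADER_RE = re.compile(r"^#n=(\d+)\s+folded=([01])\s+L=(\d+)\s*$")


def write_sfs(spec: SpectrumCounts, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n={spec.n} folded={int(spec.folded)} L={spec.L}\n")
        for i, c in zip(spec.classes, spec.counts):
            fh.write(f"{i}\t{float(c)!r}\n")


def read_sfs(path) -> SpectrumCounts:
    with open(path) as fh:
        header = fh.readline()
        m = _HEADER_RE.match(header)
        if not m:
            raise ValueError(f"malformed SFS header: {header!r}")
        n, folded, L = int(m.group(1)), bool(int(m.group(2))), int(m.group(3))
        counts = np.zeros(class_sizes(n, folded))
        for line in fh:
            if not line.strip():
                continue
            i_s, c_s = line.split("\t")
            counts[int(i_s) - 1] = float(c_s)
    return SpectrumCounts(n=n, counts=counts, folded=folded, L=L)


@dataclass
class VcfTally:
    """A tallied spectrum plus bookkeeping of skipped sites."""

    spec: SpectrumCounts
    used: int
    skipped: dict  # reason -> count


def vcf_to_sfs(path, n: int, ancestral_tag: str = "AA",
               folded: bool = False, L: int = 1) -> VcfTally:
    """Tally an SFS from the biallelic SNVs of a VCF.

    ``n`` is the fixed haploid sample count; diploid genotypes contribute two
    haploid observations (phasing is irrelevant for allele counts).  In
    unfolded mode the ancestral allele is read from the INFO field named by
    ``ancestral_tag``; sites where it matches neither REF nor ALT are
    skipped, as are monomorphic, multiallelic, non-SNV and incomplete sites.
    """
    from cyvcf2 import VCF

    skipped = {"multiallelic_or_non_snv": 0, "monomorphic": 0,
               "missing_genotypes": 0, "ancestral_unresolved": 0}
    counts = np.zeros(class_sizes(n, folded))
    used = 0
    for var in VCF(str(path)):
        if len(var.ALT) != 1 or not var.is_snp:
            skipped["multiallelic_or_non_snv"] += 1
            continue
        gts = np.asarray(var.genotype.array())[:, :-1]  # drop phasing column
        if (gts < 0).any():
            skipped["missing_genotypes"] += 1
            continue
        alleles = gts.ravel()
        if len(alleles) != n:
            skipped["missing_genotypes"] += 1
            continue
        alt_count = int((alleles == 1).sum())
        if alt_count == 0 or alt_count == n:
            skipped["monomorphic"] += 1
            continue
        if folded:
            cls = min(alt_count, n - alt_count)
        else:
            aa = var.INFO.get(ancestral_tag)
            aa = aa.upper() if isinstance(aa, str) else None
            if aa == var.REF.upper():
                cls = alt_count
            elif aa == var.ALT[0].upper():
                cls = n - alt_count
            else:
                skipped["ancestral_unresolved"] += 1
                continue
        counts[cls - 1] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable biallelic sites in the VCF")
    spec = SpectrumCounts(n=n, counts=counts, folded=folded, L=L)
    return VcfTally(spec=spec, used=used, skipped=skipped)
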