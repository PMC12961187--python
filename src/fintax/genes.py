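"""Canonical mitochondrial gene names and name normalization.

Fish mitochondrial references arrive with wildly inconsistent gene labels
("rrnS", "s-rRNA", "COi", "MT-CYB", ...).  Downstream curation and search
operate on a fixed vocabulary of the 15 marker-relevant genes: the two
rRNA genes and the 13 protein-coding genes of the vertebrate mitogenome.
"""

from __future__ import annotations

RRNA_GENES: tuple[str, ...] = ("12S rRNA", "16S rRNA")

PROTEIN_CODING_GENES: tuple[str, ...] = (
    "ND1",
    "ND2",
    "COXI",
    "COXII",
    "ATPase8",
    "ATPase6",
    "COXIII",
    "ND3",
    "ND4L",
    "ND4",
    "ND5",
    "ND6",
    "Cytb",
)

CANONICAL_GENES: tuple[str, ...] = RRNA_GENES + PROTEIN_CODING_GENES

# Alternative spellings seen in sequence records, keyed by canonical name.
# Matching is case-insensitive and ignores hyphens, underscores and spaces.
_ALTERNATIVES: dict[str, tuple[str, ...]] = {
    "12S rRNA": ("12S ribosomal RNA", "rrnS", "rrn12", "rns", "rrnaS", "s-rRNA", "SSU", "12S"),
    "16S rRNA": ("16S ribosomal RNA", "rrnL", "rrn16", "rnl", "rrnaL", "l-rRNA", "LSU", "16S"),
    "ND1": ("NADH dehydrogenase subunit 1", "NAD1", "NADH1", "NADH-I"),
    "ND2": ("NADH dehydrogenase subunit 2", "NAD2", "NADH2", "NADH-2"),
    "COXI": ("cytochrome c oxidase subunit 1", "COX1", "COI", "CO1", "COX-1"),
    "COXII": ("cytochrome c oxidase subunit 2", "COX2", "COII", "CO2", "COX-II"),
    "ATPase8": ("ATP synthase F0 subunit 8", "ATP8", "apt8", "MTATP8", "stp8", "ATPase-8", "AT8"),
    "ATPase6": ("ATP synthase F0 subunit 6", "ATP6", "MTATP6", "ATPase-6", "AT6"),
    "COXIII": ("cytochrome c oxidase subunit 3", "COX3", "COIII", "CO3", "COX-III"),
    "ND3": ("NADH dehydrogenase subunit 3", "NAD3", "NADH3", "NADH-3"),
    "ND4L": ("NADH dehydrogenase subunit 4L", "NAD4L", "NADH4L", "NADH-4L", "ND41", "NA4L"),
    "ND4": ("NADH dehydrogenase subunit 4", "NAD4", "NADH4", "NADH-4"),
    "ND5": ("NADH dehydrogenase subunit 5", "NAD5", "NADH5", "NADH-5", "NND5", "MD5"),
    "ND6": ("NADH dehydrogenase subunit 6", "NAD6", "NADH6", "NADH-6"),
    "Cytb": ("cytochrome b", "MT-CYB", "cyto B", "Cyt-B", "CYBT", "ctb", "cob", "Cb"),
}


def _key(name: str) -> str:
    return "".join(ch for ch in name.casefold() if ch not in " -_")


_LOOKUP: dict[str, str] = {}
for _canon in CANONICAL_GENES:
    _LOOKUP[_key(_canon)] = _canon
    for _alt in _ALTERNATIVES[_canon]:
        _LOOKUP.setdefault(_key(_alt), _canon)


def normalize_gene_name(raw: str) -> str | None:
    """Map a raw gene label to its canonical name, or ``None`` if unknown.

    Matching is case-insensitive and ignores hyphens/underscores/spaces,
    so ``"rrnS"`` -> ``"12S rRNA"`` and ``"COi"`` -> ``"COXI"``.
    """
    if not raw:
        raise ValueError("gene name must be non-empty")
    return _LOOKUP.get(_key(raw))


def is_canonical_gene(name: str) -> bool:
    return name in CANONICAL_GENES
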