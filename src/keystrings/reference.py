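"""Reference phylum-level key K-string sharing counts for metazoan
mitochondrial proteomes.

These are the published set sizes and pairwise shared counts for the
phylum-specific key 5-string sets of eleven metazoan phyla (full NCBI
mitochondrial snapshot; not recomputable from the synthetic fixtures).  They
serve as inputs for the sharing/bias arithmetic: diagonal sizes, the shared
counts of the upper triangle, and the derived bias percentages of the lower
triangle.
"""

from __future__ import annotations

import numpy as np

from .keys import SharingTable, summarize_sharing

METAZOAN_PHYLA = (
    "Annelida", "Chelicerata", "Coelenterata", "Crustacea", "Echinodermata",
    "Hexapoda", "Mollusca", "Nematoda", "Platyhelminthes", "Porifera",
    "Vertebrate",
)

#: Phylum-specific key 5-string set sizes (diagonal of the sharing table).
KEYSET_SIZES = (4656, 2987, 2642, 2827, 3340, 3197, 1956, 2545, 4326, 4198, 3055)

#: Upper-triangle pairwise shared counts |A & B|, row-major over phylum pairs.
SHARED_COUNTS: dict[tuple[str, str], int] = {
    ("Annelida", "Chelicerata"): 721,
    ("Annelida", "Coelenterata"): 308,
    ("Annelida", "Crustacea"): 748,
    ("Annelida", "Echinodermata"): 669,
    ("Annelida", "Hexapoda"): 782,
    ("Annelida", "Mollusca"): 641,
    ("Annelida", "Nematoda"): 330,
    ("Annelida", "Platyhelminthes"): 367,
    ("Annelida", "Porifera"): 510,
    ("Annelida", "Vertebrate"): 611,
    ("Chelicerata", "Coelenterata"): 349,
    ("Chelicerata", "Crustacea"): 911,
    ("Chelicerata", "Echinodermata"): 718,
    ("Chelicerata", "Hexapoda"): 1091,
    ("Chelicerata", "Mollusca"): 611,
    ("Chelicerata", "Nematoda"): 534,
    ("Chelicerata", "Platyhelminthes"): 579,
    ("Chelicerata", "Porifera"): 559,
    ("Chelicerata", "Vertebrate"): 511,
    ("Coelenterata", "Crustacea"): 308,
    ("Coelenterata", "Echinodermata"): 384,
    ("Coelenterata", "Hexapoda"): 328,
    ("Coelenterata", "Mollusca"): 274,
    ("Coelenterata", "Nematoda"): 193,
    ("Coelenterata", "Platyhelminthes"): 259,
    ("Coelenterata", "Porifera"): 777,
    ("Coelenterata", "Vertebrate"): 291,
    ("Crustacea", "Echinodermata"): 674,
    ("Crustacea", "Hexapoda"): 1117,
    ("Crustacea", "Mollusca"): 612,
    ("Crustacea", "Nematoda"): 342,
    ("Crustacea", "Platyhelminthes"): 438,
    ("Crustacea", "Porifera"): 500,
    ("Crustacea", "Vertebrate"): 552,
    ("Echinodermata", "Hexapoda"): 682,
    ("Echinodermata", "Mollusca"): 491,
    ("Echinodermata", "Nematoda"): 343,
    ("Echinodermata", "Platyhelminthes"): 503,
    ("Echinodermata", "Porifera"): 594,
    ("Echinodermata", "Vertebrate"): 685,
    ("Hexapoda", "Mollusca"): 559,
    ("Hexapoda", "Nematoda"): 454,
    ("Hexapoda", "Platyhelminthes"): 464,
    ("Hexapoda", "Porifera"): 549,
    ("Hexapoda", "Vertebrate"): 576,
    ("Mollusca", "Nematoda"): 291,
    ("Mollusca", "Platyhelminthes"): 345,
    ("Mollusca", "Porifera"): 418,
    ("Mollusca", "Vertebrate"): 428,
    ("Nematoda", "Platyhelminthes"): 485,
    ("Nematoda", "Porifera"): 309,
    ("Nematoda", "Vertebrate"): 195,
    ("Platyhelminthes", "Porifera"): 448,
    ("Platyhelminthes", "Vertebrate"): 223,
    ("Porifera", "Vertebrate"): 435,
}


def metazoan_sharing_table() -> SharingTable:
    """The reference sharing table rebuilt from sizes and shared counts."""
    n = len(METAZOAN_PHYLA)
    shared = np.zeros((n, n))
    idx = {p: i for i, p in enumerate(METAZOAN_PHYLA)}
    for i in range(n):
        shared[i, i] = KEYSET_SIZES[i]
    for (a, b), v in SHARED_COUNTS.items():
        shared[idx[a], idx[b]] = shared[idx[b], idx[a]] = v
    return SharingTable.from_counts(
        list(METAZOAN_PHYLA), list(KEYSET_SIZES), shared
    )


def metazoan_sharing_summary() -> dict[str, float]:
    return summarize_sharing(metazoan_sharing_table())
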