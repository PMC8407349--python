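"""Reference genome registry for the ganjang (Korean soy sauce) community.

Seventeen reference genomes — ten high-quality metagenome-assembled genomes
(MAGs) and seven isolate genomes — representing the major bacteria and fungi of
a meju-brick/brine fermentation: halophilic lactic acid bacteria
(*Tetragenococcus*), facultatively aerobic halophiles (*Chromohalobacter*,
*Halomonas*, *Marinobacter*, Idiomarinaceae, Alteromonadaceae), meju-derived
*Bacillus* and relatives, and the halotolerant yeasts *Debaryomyces*,
*Wickerhamomyces* and *Aspergillus*.

``marker_copies`` is the per-genome count of the amplicon/qPCR marker gene
(16S rRNA for bacteria, ITS for fungi); ``marker_copies_estimated`` flags
copy numbers taken from the most closely related complete genome rather than
resolved from the genome assembly itself.
"""

from __future__ import annotations

import pandas as pd

from .containers import validate_genome_registry

# genome_id, taxon_label, domain, source, genome_size_bp, marker_copies, estimated
_GENOMES = [
    ("KG1", "Bacillus sp. KG1", "bacteria", "MAG", 3_100_000, 10, True),
    ("KG2", "Bacillus sp. KG2", "bacteria", "MAG", 3_100_000, 8, True),
    ("KG3", "Bacillus sp. KG3", "bacteria", "MAG", 4_500_000, 9, True),
    ("KG4", "Corynebacterium sp. KG4", "bacteria", "MAG", 3_000_000, 5, True),
    ("KG5", "Staphylococcus sp. KG5", "bacteria", "MAG", 3_100_000, 6, True),
    ("KG6", "Halomonas sp. KG6", "bacteria", "MAG", 3_000_000, 4, True),
    ("KG7", "Virgibacillus sp. KG7", "bacteria", "MAG", 3_600_000, 8, True),
    ("KG8", "Alteromonadaceae sp. KG8", "bacteria", "MAG", 4_900_000, 3, True),
    ("KG9", "Idiomarinaceae sp. KG9", "bacteria", "MAG", 4_200_000, 4, True),
    ("KG10", "Micrococcaceae sp. KG10", "bacteria", "MAG", 3_100_000, 6, True),
    ("KG11", "Tetragenococcus sp. KG11", "bacteria", "isolate", 2_400_000, 5, True),
    ("KG12", "Tetragenococcus sp. KG12", "bacteria", "isolate", 2_500_000, 5, True),
    ("KG13", "Chromohalobacter sp. KG13", "bacteria", "isolate", 3_500_000, 5, True),
    ("KG14", "Marinobacter sp. KG14", "bacteria", "isolate", 3_500_000, 3, True),
    ("KG15", "Aspergillus sp. KG15", "fungi", "isolate", 38_000_000, 3, True),
    ("KG16", "Wickerhamomyces sp. KG16", "fungi", "isolate", 23_900_000, 1, False),
    ("C11", "Debaryomyces sp. C11", "fungi", "isolate", 24_500_000, 5, False),
]


def ganjang_genome_registry() -> pd.DataFrame:
    """The 17-genome ganjang reference registry as a validated DataFrame."""
    frame = pd.DataFrame(
        _GENOMES,
        columns=[
            "genome_id",
            "taxon_label",
            "domain",
            "source",
            "genome_size_bp",
            "marker_copies",
            "marker_copies_estimated",
        ],
    ).set_index("genome_id")
    return validate_genome_registry(frame)
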