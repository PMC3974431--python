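"""Reference bee-forewing study design and its cross-validation count table.

The comparative dataset behind this pipeline is a curated collection of 360
female bee forewings spanning 6 families, 15 subfamilies and 109 species
(all with three submarginal cells, at most 20 specimens per subfamily and 5
per species, *Melitta* sampled exhaustively).  The raw landmark coordinates
were never deposited, so only the printed composition and the printed
leave-one-out cross-validation counts are available; they are stored here
as plain data and serve two purposes:

* worked examples — hit ratios and bookkeeping totals recomputed from the
  printed counts through the same :class:`~wingmorph.stats.ConfusionMatrix`
  machinery used for fresh analyses;
* the template for the synthetic generator's default group sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import ConfusionMatrix

__all__ = [
    "study_design",
    "subfamily_sizes",
    "design_totals",
    "reference_confusion",
]

# (family, subfamily, species, n_specimens); daggered names are fossils
_DESIGN: tuple[tuple[str, str, str, int], ...] = (
    ("Andrenidae", "Andreninae", "Andrena bicolor", 5),
    ("Andrenidae", "Andreninae", "Andrena boyerella", 5),
    ("Andrenidae", "Andreninae", "Andrena flavipes", 5),
    ("Andrenidae", "Andreninae", "Andrena fulva", 5),
    ("Andrenidae", "Oxaeinae", "Oxaea flavescens", 1),
    ("Andrenidae", "Oxaeinae", "Oxaea fuscescens", 1),
    ("Andrenidae", "Oxaeinae", "Oxaea sp.", 1),
    ("Andrenidae", "Oxaeinae", "Protoxaea gloriosa", 2),
    ("Andrenidae", "Panurginae", "Borgatomelissa brevipennis", 1),
    ("Andrenidae", "Panurginae", "Melitturga clavicornis", 1),
    ("Andrenidae", "Panurginae", "Melitturga taurica", 5),
    ("Andrenidae", "Panurginae", "Anthrenoides sp.", 2),
    ("Andrenidae", "Panurginae", "Parapsaenythia puncticutis", 2),
    ("Apidae", "Apinae", "Apis florea", 5),
    ("Apidae", "Apinae", "Bombus mendax", 5),
    ("Apidae", "Apinae", "Melissodes confusa", 5),
    ("Apidae", "Apinae", "Anthophora plumipes", 5),
    ("Apidae", "Apinae", "Paleohabropoda oudardi †", 1),
    ("Apidae", "Apinae", "Anthophorula persephone †", 1),
    ("Apidae", "Apinae", "Bombus randeckensis †", 1),
    ("Apidae", "Apinae", "Electrapis krishnorum †", 1),
    ("Apidae", "Apinae", "Electrapis meliponoides †", 1),
    ("Apidae", "Apinae", "Electrobombus samlandensis †", 1),
    ("Apidae", "Apinae", "Eufriesea melissiflora †", 1),
    ("Apidae", "Apinae", "Melikertes stilbonotus †", 1),
    ("Apidae", "Apinae", "Melissites trigona †", 1),
    ("Apidae", "Apinae", "Protobombus basilaris †", 1),
    ("Apidae", "Apinae", "Probombus hirsutus †", 1),
    ("Apidae", "Apinae", "Succinapis goeleti †", 1),
    ("Apidae", "Apinae", "Thaumastobombus andreniformis †", 2),
    ("Apidae", "Nomadinae", "Epeolus cruciger", 5),
    ("Apidae", "Nomadinae", "Nomada fabriciana", 5),
    ("Apidae", "Nomadinae", "Nomada flava", 5),
    ("Apidae", "Nomadinae", "Nomada goodeniana", 5),
    ("Apidae", "Xylocopinae", "Ceratina chloris", 5),
    ("Apidae", "Xylocopinae", "Ceratina dallatorreana", 5),
    ("Apidae", "Xylocopinae", "Xylocopa olivieri", 5),
    ("Apidae", "Xylocopinae", "Xylocopa violacea", 5),
    ("Colletidae", "Colletinae", "Colletes cunicularius", 5),
    ("Colletidae", "Colletinae", "Colletes daviesanus", 5),
    ("Colletidae", "Colletinae", "Colletes succinctus", 5),
    ("Colletidae", "Colletinae", "Leioproctus sp.", 5),
    ("Colletidae", "Diphaglossinae", "Cadeguala occidentalis", 1),
    ("Colletidae", "Diphaglossinae", "Caupolicana gayi", 5),
    ("Colletidae", "Diphaglossinae", "Caupolicana yarrowi", 3),
    ("Colletidae", "Diphaglossinae", "Crawfordapis luctuosa", 2),
    ("Colletidae", "Diphaglossinae", "Diphaglossa gayi", 3),
    ("Colletidae", "Diphaglossinae", "Mydrosoma bohartorum", 1),
    ("Colletidae", "Diphaglossinae", "Ptiloglossa guinnae", 1),
    ("Colletidae", "Diphaglossinae", "Ptiloglossa pretiosa", 4),
    ("Halictidae", "Halictinae", "Augochlorella striata", 5),
    ("Halictidae", "Halictinae", "Halictus ligatus", 5),
    ("Halictidae", "Halictinae", "Ruizantheda nigrocaerulea", 5),
    ("Halictidae", "Halictinae", "Thrinchostoma kandti", 5),
    ("Halictidae", "Halictinae", "Cyrtapis anomala †", 1),
    ("Halictidae", "Halictinae", "Electrolictus antiquus †", 1),
    ("Halictidae", "Halictinae", "Halictus petrefactus †", 1),
    ("Halictidae", "Halictinae", "Ocymoromelitta florissantella †", 1),
    ("Halictidae", "Halictinae", "Ocymoromelitta sorella †", 1),
    ("Halictidae", "Nomiinae", "Dieunomia nevadensis", 1),
    ("Halictidae", "Nomiinae", "Halictonomia decemmaculata", 2),
    ("Halictidae", "Nomiinae", "Lipotriches australica", 1),
    ("Halictidae", "Nomiinae", "Lipotriches modesta", 5),
    ("Halictidae", "Nomiinae", "Nomia melanderi", 1),
    ("Halictidae", "Nomiinae", "Nomia diversipes", 5),
    ("Halictidae", "Nomiinae", "Pseudapis diversipes", 5),
    ("Halictidae", "Nomioidinae", "Ceylalictus variegatus", 5),
    ("Halictidae", "Nomioidinae", "Nomioides facilis", 5),
    ("Halictidae", "Nomioidinae", "Nomioides minutissimus", 1),
    ("Halictidae", "Rophitinae", "Systropha curvicornis", 2),
    ("Halictidae", "Rophitinae", "Systropha maroccana", 3),
    ("Halictidae", "Rophitinae", "Systropha pici", 2),
    ("Halictidae", "Rophitinae", "Systropha planidens", 5),
    ("Halictidae", "Rophitinae", "Systropha sp.", 5),
    ("Megachilidae", "Fideliinae", "Fidelia kobrowi", 5),
    ("Megachilidae", "Fideliinae", "Fidelia paradoxa", 5),
    ("Megachilidae", "Fideliinae", "Fidelia villosa", 1),
    ("Megachilidae", "Fideliinae", "Fideliopsis major", 2),
    ("Melittidae", "Meganomiinae", "Meganomia andersoni", 2),
    ("Melittidae", "Meganomiinae", "Meganomia binghami", 5),
    ("Melittidae", "Melittinae", "Rediviva intermixta", 5),
    ("Melittidae", "Melittinae", "Rediviva longimanus", 3),
    ("Melittidae", "Melittinae", "Melitta americana", 3),
    ("Melittidae", "Melittinae", "Melitta arrogans", 5),
    ("Melittidae", "Melittinae", "Melitta bicollaris", 5),
    ("Melittidae", "Melittinae", "Melitta californica", 1),
    ("Melittidae", "Melittinae", "Melitta cameroni", 5),
    ("Melittidae", "Melittinae", "Melitta dimidiata", 5),
    ("Melittidae", "Melittinae", "Melitta eickworti", 3),
    ("Melittidae", "Melittinae", "Melitta ezoana", 5),
    ("Melittidae", "Melittinae", "Melitta haemorrhoidalis", 5),
    ("Melittidae", "Melittinae", "Melitta hispanica", 5),
    ("Melittidae", "Melittinae", "Melitta harrietae", 5),
    ("Melittidae", "Melittinae", "Melitta japonica", 4),
    ("Melittidae", "Melittinae", "Melitta magnifica", 3),
    ("Melittidae", "Melittinae", "Melitta melittoides", 2),
    ("Melittidae", "Melittinae", "Melitta melanura", 5),
    ("Melittidae", "Melittinae", "Melitta murciana", 5),
    ("Melittidae", "Melittinae", "Melitta seitzi", 1),
    ("Melittidae", "Melittinae", "Melitta schultzei", 1),
    ("Melittidae", "Melittinae", "Melitta sibirica", 5),
    ("Melittidae", "Melittinae", "Melitta aegyptiaca", 5),
    ("Melittidae", "Melittinae", "Melitta leporina", 5),
    ("Melittidae", "Melittinae", "Melitta maura", 5),
    ("Melittidae", "Melittinae", "Melitta nigricans", 5),
    ("Melittidae", "Melittinae", "Melitta schmiedeknechti", 5),
    ("Melittidae", "Melittinae", "Melitta tricincta", 5),
    ("Melittidae", "Melittinae", "Melitta avontuurensis", 1),
    ("Melittidae", "Melittinae", "Melitta richtersveldensis", 5),
)

_SUBFAMILIES: tuple[str, ...] = (
    "Andreninae",
    "Apinae",
    "Colletinae",
    "Diphaglossinae",
    "Fideliinae",
    "Halictinae",
    "Meganomiinae",
    "Melittinae",
    "Nomadinae",
    "Nomiinae",
    "Nomioidinae",
    "Oxaeinae",
    "Panurginae",
    "Rophitinae",
    "Xylocopinae",
)

# leave-one-out cross-validation counts in LDA space with subfamily grouping
# (rows = original group, columns = predicted group), subfamilies as above
_CONFUSION_COUNTS = np.zeros((15, 15), dtype=int)
_IDX = {g: i for i, g in enumerate(_SUBFAMILIES)}
for _g, _row in {
    "Andreninae": {"Andreninae": 20},
    "Apinae": {"Apinae": 33, "Diphaglossinae": 1},
    "Colletinae": {"Colletinae": 20},
    "Diphaglossinae": {"Diphaglossinae": 19, "Apinae": 1},
    "Fideliinae": {"Fideliinae": 13},
    "Halictinae": {"Halictinae": 24, "Apinae": 1},
    "Meganomiinae": {"Meganomiinae": 7},
    "Melittinae": {"Melittinae": 117},
    "Nomadinae": {"Nomadinae": 20},
    "Nomiinae": {"Nomiinae": 20},
    "Nomioidinae": {"Nomioidinae": 11},
    "Oxaeinae": {"Oxaeinae": 5},
    "Panurginae": {"Panurginae": 10, "Andreninae": 1},
    "Rophitinae": {"Rophitinae": 16, "Halictinae": 1},
    "Xylocopinae": {"Xylocopinae": 20},
}.items():
    for _pred, _n in _row.items():
        _CONFUSION_COUNTS[_IDX[_g], _IDX[_pred]] = _n
_CONFUSION_COUNTS.setflags(write=False)


def study_design() -> pd.DataFrame:
    """Per-species composition of the reference dataset as a DataFrame."""
    return pd.DataFrame(_DESIGN, columns=["family", "subfamily", "species", "n"])


def subfamily_sizes() -> dict[str, int]:
    """Specimens per subfamily, in fixed subfamily order."""
    df = study_design()
    sizes = df.groupby("subfamily")["n"].sum()
    return {g: int(sizes[g]) for g in _SUBFAMILIES}


def design_totals() -> dict[str, int]:
    """Bookkeeping totals of the reference design.

    ``n_melitta`` counts specimens of the genus *Melitta* only;
    ``n_melittinae`` is the whole subfamily (including *Rediviva*).
    """
    df = study_design()
    genus = df["species"].str.split().str[0]
    return {
        "n_specimens": int(df["n"].sum()),
        "n_species": int(len(df)),
        "n_subfamilies": int(df["subfamily"].nunique()),
        "n_families": int(df["family"].nunique()),
        "n_melitta": int(df.loc[genus == "Melitta", "n"].sum()),
        "n_melittinae": int(df.loc[df["subfamily"] == "Melittinae", "n"].sum()),
    }


def reference_confusion() -> ConfusionMatrix:
    """The reference study's printed LOO cross-validation counts."""
    return ConfusionMatrix(groups=_SUBFAMILIES, counts=_CONFUSION_COUNTS.copy())
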