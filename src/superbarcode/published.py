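"""Worked-example data: a published genus-level barcoding comparison.

Per-species tree-based discrimination verdicts (monophyly yes/no with the
bootstrap support of the species clade) for the 21 maple (*Acer*) species
sampled with multiple individuals, across four barcode datasets: the whole
plastome, the standard plastid barcode combination *matK* + *rbcL* +
*trnH*-*psbA*, the complete nrDNA cistron, and ITS alone. This printed
table is used as input by the validation suite and the reproduction
script: feeding it through :func:`~superbarcode.treedisc.resolution`,
:func:`~superbarcode.treedisc.compare_datasets` and
:func:`~superbarcode.treedisc.support_summary` recomputes the dataset
resolutions, the species gained by the plastome over the standard
barcodes, and the support histograms.
"""

from __future__ import annotations

from .treedisc import MonophylyVerdict

DATASETS = ("plastome", "matK+rbcL+trnH-psbA", "nrDNA", "ITS")

# species -> ((monophyletic, support) per dataset, in DATASETS order)
_TABLE: dict[str, tuple[tuple[bool, float | None], ...]] = {
    "Acer amplum": ((True, 100), (True, 78), (False, None), (False, None)),
    "Acer caudatum": ((True, 100), (True, 100), (True, 100), (True, 100)),
    "Acer coriaceifolium": ((False, None), (False, None), (True, 99), (True, 96)),
    "Acer duplicatoserratum var. chinense": (
        (True, 100),
        (True, 62),
        (True, 99),
        (True, 98),
    ),
    "Acer fabri": ((True, 85), (False, None), (True, 99), (False, None)),
    "Acer flabellatum": ((True, 100), (False, None), (False, None), (False, None)),
    "Acer griseum": ((True, 100), (True, 100), (True, 91), (False, None)),
    "Acer grosseri": ((True, 100), (True, 95), (True, 63), (True, 69)),
    "Acer henryi": ((True, 100), (True, 100), (True, 100), (True, 100)),
    "Acer japonicum": ((True, 100), (False, None), (False, None), (False, None)),
    "Acer laurinum": ((True, 100), (True, 100), (True, 100), (True, 100)),
    "Acer maximowiczii": ((True, 100), (False, None), (True, 100), (True, 100)),
    "Acer miaotaiense": ((True, 100), (True, 62), (True, 100), (True, 100)),
    "Acer oblongum": ((True, 100), (False, None), (True, 99), (True, 77)),
    "Acer oliverianum": ((False, None), (False, None), (True, 100), (True, 90)),
    "Acer shenkanense": ((True, 100), (True, 64), (True, 100), (True, 100)),
    "Acer stachyophyllum subsp. betulifolium": (
        (True, 100),
        (True, 100),
        (True, 100),
        (True, 100),
    ),
    "Acer sterculiaceum subsp. franchetii": (
        (True, 100),
        (True, 94),
        (True, 100),
        (False, None),
    ),
    "Acer tataricum": ((True, 100), (True, 100), (True, 100), (True, 99)),
    "Acer truncatum": ((True, 100), (True, 85), (True, 90), (True, 86)),
    "Acer tutcheri": ((True, 100), (False, None), (False, None), (False, None)),
}


def acer_verdicts(dataset: str) -> list[MonophylyVerdict]:
    """The printed verdict column for one dataset as MonophylyVerdict objects.

    Individual counts are not printed per species; the verdict semantics
    only require n_individuals >= 2, so 2 is recorded.
    """
    col = DATASETS.index(dataset)
    return [
        MonophylyVerdict(
            species=sp,
            monophyletic=cells[col][0],
            support=float(cells[col][1]) if cells[col][0] else None,
            n_individuals=2,
        )
        for sp, cells in _TABLE.items()
    ]
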