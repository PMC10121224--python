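import math

import numpy as np
import pytest

from organoscreen.model import (
    AssayKind,
    CellLine,
    PlateInfo,
    PlateSet,
    Treatment,
    WellRecord,
)


def make_plate(
    plate_id="P1",
    wt_dmso=(), rd_dmso=(), par_dmso=(),
    compound_wells=(),
    assay_kind=AssayKind.DISEASE_ASSAY,
    replicate=0,
):
    """Build a small single-plate PlateSet from explicit well intensities.

    ``wt_dmso``/``rd_dmso``/``par_dmso`` are (gfp, dapi) pairs;
    ``compound_wells`` are (cell_line, compound_id, conc, gfp, dapi) tuples.
    Wells are laid out row-major from the plate origin.
    """
    records = []
    pos = iter(range(32 * 48))

    def place(line, treatment, cid, conc, gfp, dapi, masked=False):
        i = next(pos)
        records.append(
            WellRecord(
                plate_id=plate_id, row=i // 48, col=i % 48,
                cell_line=line, treatment=treatment,
                compound_id=cid, concentration=conc,
                gfp=gfp, dapi=dapi, masked=masked,
            )
        )

    for gfp, dapi in wt_dmso:
        place(CellLine.WT, Treatment.DMSO, None, None, gfp, dapi)
    for gfp, dapi in rd_dmso:
        place(CellLine.RD16, Treatment.DMSO, None, None, gfp, dapi)
    for gfp, dapi in par_dmso:
        place(CellLine.PARENTAL, Treatment.DMSO, None, None, gfp, dapi)
    for line, cid, conc, gfp, dapi in compound_wells:
        place(line, Treatment.COMPOUND, cid, conc, gfp, dapi)

    return PlateSet.from_records(
        records,
        {plate_id: PlateInfo(assay_kind=assay_kind, replicate_index=replicate)},
    )


def random_plateset(seed: int, n_plates: int = 2, n_wells: int = 40) -> PlateSet:
    """A randomized multi-plate PlateSet exercising every field combination."""
    rng = np.random.default_rng(seed)
    records = []
    info = {}
    kinds = list(AssayKind)
    for p in range(n_plates):
        pid = f"RP{p}"
        info[pid] = PlateInfo(
            assay_kind=kinds[int(rng.integers(len(kinds)))],
            replicate_index=int(rng.integers(3)),
        )
        positions = rng.choice(32 * 48, size=n_wells, replace=False)
        for i, posn in enumerate(positions):
            dmso = bool(rng.random() < 0.4)
            records.append(
                WellRecord(
                    plate_id=pid,
                    row=int(posn) // 48,
                    col=int(posn) % 48,
                    cell_line=list(CellLine)[int(rng.integers(3))],
                    treatment=Treatment.DMSO if dmso else Treatment.COMPOUND,
                    compound_id=None if dmso else f"C{i % 7}",
                    concentration=None if dmso else float(10 ** rng.uniform(-8, -4)),
                    gfp=float(rng.uniform(0, 2000)),
                    dapi=float(rng.uniform(0, 2000)),
                    masked=bool(rng.random() < 0.1),
                )
            )
    return PlateSet.from_records(records, info)


@pytest.fixture(scope="session")
def small_campaign():
    """A modest noisy campaign with ground truth, shared across tests."""
    from organoscreen.simulate import SimConfig, simulate_campaign

    config = SimConfig(n_compounds=60, seed=42)
    plates, truth = simulate_campaign(config)
    return config, plates, truth
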