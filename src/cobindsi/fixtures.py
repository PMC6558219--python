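"""Packaged reference data.

Two kinds of fixtures ship with the package:

* ``table1a``/``table1b`` — the published top-30 fold-change tables for the
  IFNα+LPS and IFNγ+LPS responses in vascular smooth muscle cells, including
  the promoter-site dots and the synergy (SI) marks. They are the only
  printed input/output pair that exercises the SI statistic end to end, so
  they serve as a standing regression fixture.
* ``default_motifs`` — three small synthetic consensus-style count matrices
  (GAS, ISRE, NFκB), used by the simulator and as default scan matrices.
  They are constructed stand-ins, not the published HOMER/JASPAR profiles;
  any real JASPAR PFM file can be supplied instead.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import PWM, parse_jaspar_pfm

_MOTIF_FILES = {
    "GAS": "GAS_synthetic.jaspar",
    "ISRE": "ISRE_synthetic.jaspar",
    "NFKB": "NFKB_synthetic.jaspar",
}


def _data_path(*parts: str):
    return resources.files("cobindsi").joinpath("data", *parts)


def load_table1(which: str) -> pd.DataFrame:
    """Load the published top-30 FC table ``"a"`` (IFNα+LPS) or ``"b"`` (IFNγ+LPS).

    Columns: gene, fc_ifn, fc_lps, fc_combo, gas/isre/nfkb promoter-site
    indicators (0/1) and si_marked (0/1, the published synergy mark).
    """
    which = which.lower()
    if which not in ("a", "b"):
        raise ValueError("which must be 'a' or 'b'")
    with resources.as_file(_data_path(f"table1{which}.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_published_overlaps() -> pd.DataFrame:
    """Published mode-overlap and common-gene-overlap figures.

    List sizes are as printed; intersections are the unique integers that
    reproduce the printed percentages under the stated method.
    """
    with resources.as_file(_data_path("fig_overlaps.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def default_motifs(pseudocount: float = 0.0) -> dict[str, PWM]:
    """The packaged synthetic GAS/ISRE/NFκB count matrices as PWMs."""
    pwms = {}
    for motif_class, fname in _MOTIF_FILES.items():
        with resources.as_file(_data_path("motifs", fname)) as path:
            pwms[motif_class] = parse_jaspar_pfm(path, motif_class, pseudocount)
    return pwms
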