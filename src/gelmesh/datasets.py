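"""Packaged reference tables.

Two published summary tables for the sixteen nanogel systems
(PN-0/CA-5/CA-15/CA-20 × pH L/H × 298/310 K) are shipped as CSVs:

* ``descriptor_table`` — simulation-derived descriptors: IBU diffusion
  coefficient D (10^-7 cm^2/s), dissociated fraction (%), polymer–polymer
  and polymer–IBU hydrogen-bond counts, and pore descriptors PLD/MPD
  (mean ± SD, Å).
* ``kinetics_table`` — kinetic-model fit parameters of the measured
  urea-free release curves (zero-order, first-order, Higuchi and
  Korsmeyer–Peppas k/n with R²).

These printed values serve as generating parameters for the synthetic
scenarios and as join keys for the correlation analysis.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .release import SystemID


def _load(name: str) -> pd.DataFrame:
    with resources.files("gelmesh").joinpath("data", name).open() as fh:
        df = pd.read_csv(fh)
    df["material"] = [SystemID.parse(s).material for s in df["system_id"]]
    return df


def descriptor_table() -> pd.DataFrame:
    """Per-system MD descriptors (D, f_det, H-bond counts, PLD, MPD)."""
    return _load("descriptor_table.csv")


def kinetics_table() -> pd.DataFrame:
    """Per-system release kinetic-fit parameters for the four models."""
    return _load("kinetics_table.csv")
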