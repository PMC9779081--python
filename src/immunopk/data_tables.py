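"""Bundled parameter tables: blood PK rates per particle size, particle metadata.

The blood table holds the fitted biexponential parameters for 20-, 30-
and 100-nm BNF particles (with uncertainties); the dependent rates are
re-derived exactly from (lambda_b, lambda_p, K_pb) when building
parameter objects, since the printed K_el/K_bp columns are rounded.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from io import BytesIO

import pandas as pd

from .errors import CorruptedFixtureError, MissingParameterError
from .two_compartment import TwoCompartmentParams

__all__ = ["load_blood_pk_table", "blood_pk_params", "load_particle_table"]

_CHECKSUMS = {
    "blood_pk_rates.csv": "0bde5f978eee467545a30322abafa6c04c9f310c26888fd3b7728702b9f1b5d8",
    "particles.csv": "79b84f53aa031e49f81e0db3b7ad7bf8858e703716efec88ff5b6b8fdc998c37",
}


def _read_fixture(name: str) -> pd.DataFrame:
    raw = (resources.files("immunopk.data") / name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise CorruptedFixtureError(f"{name} checksum mismatch: {digest}")
    return pd.read_csv(BytesIO(raw))


def load_blood_pk_table() -> pd.DataFrame:
    """Fitted blood-PK parameters by particle diameter, with uncertainties."""
    return _read_fixture("blood_pk_rates.csv")


def blood_pk_params(diameter_nm: int, X0: float = 100.0) -> TwoCompartmentParams:
    """Two-compartment parameters for one bundled particle size (20, 30 or 100 nm)."""
    table = load_blood_pk_table()
    sub = table[table["diameter_nm"] == diameter_nm]
    if len(sub) != 1:
        raise MissingParameterError(
            f"no bundled blood-PK row for diameter {diameter_nm} nm"
        )
    row = sub.iloc[0]
    return TwoCompartmentParams.from_eigen(
        float(row["lambda_b"]), float(row["lambda_p"]), float(row["K_pb"]), X0=X0
    )


def load_particle_table() -> pd.DataFrame:
    """Physicochemical metadata of the BNF particle configurations.

    Hydrodynamic diameter, polydispersity, zeta potential and protein
    load; carried for provenance only — nothing in the kinetic model
    reads these.
    """
    return _read_fixture("particles.csv")
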