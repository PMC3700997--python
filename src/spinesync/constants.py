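"""Physical constants and unit conversions.

Internal unit conventions:

* electrical side — mV, ms, µm, mM, nS
* biochemical side — M, s

All conversions between the two live here or in :mod:`spinesync.coupling`;
no other module hard-codes a unit factor.
"""

#: Faraday constant, C/mol.
FARADAY_C_PER_MOL = 96489.0

#: Faraday constant as printed in the thin-shell calcium balance, C/mmol.
FARADAY_C_PER_MMOL = 96.489

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: femtoliters per liter
FL_PER_L = 1e15

MS_PER_S = 1e3
S_PER_MS = 1e-3
M_PER_MM = 1e-3
MM_PER_M = 1e3


def mm_per_ms_to_m_per_s(x: float) -> float:
    """Convert a concentration rate from mM/ms to M/s (factor 1)."""
    return x * M_PER_MM * MS_PER_S


def m_per_s_to_mm_per_ms(x: float) -> float:
    return x * MM_PER_M * S_PER_MS
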