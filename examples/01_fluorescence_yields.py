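"""Derive PSII quantum yields from raw PAM fluorescence values.

Builds a tiny measurement table, derives F_v/F_m, Phi_PSII and Phi_NPQ,
and shows how physiologically impossible records are flagged instead of
dropped.
"""

import pandas as pd

from dodder import fluorescence as fl

raw = pd.DataFrame(
    {
        "species": ["Cuscuta_monogyna"] * 2 + ["Cuscuta_australis"],
        "individual": ["A", "B", "A"],
        "stage": ["y", "o", "y"],
        "F_o": [200.0, 350.0, 900.0],
        "F_m": [1000.0, 800.0, 500.0],   # third record: F_o > F_m (impossible)
        "F_s": [400.0, 420.0, 400.0],
        "F_m_prime": [500.0, 450.0, 500.0],
    }
)

out = fl.derive_table(raw)
print(out[["species", "stage", "fv_fm", "phi_psii", "phi_npq", "valid"]].round(3))
print()
print("Row 0: F_v/F_m = (1000-200)/1000 = 0.8 -> healthy dark-adapted PSII;")
print("Phi_PSII = 1-400/500 = 0.2 of absorbed light drives photochemistry and")
print("Phi_NPQ = 400/500-400/1000 = 0.4 is dissipated as regulated heat.")
print("Row 2 is flagged invalid (F_o > F_m) and would be excluded downstream.")
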