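"""Estimate intrinsic aqueous solubility from melting point and logP with
the general solubility equation, and propagate melting-point model error
into the solubility estimate.
"""

from mpminer.gse import GSEInput, gse_error_contribution, gse_logs

for mp_c, logp in [(25.0, 0.0), (125.0, 2.3), (155.0, 3.0)]:
    logs = gse_logs(GSEInput(mp_c, logp))
    print(f"MP = {mp_c:6.1f} °C, logP = {logp:4.1f}  ->  "
          f"logS = {logs:6.2f} (mol/L, log10)")

for mp_rmse in (30.0, 35.0):
    print(f"an MP model RMSE of {mp_rmse:.0f} °C contributes "
          f"{gse_error_contribution(mp_rmse):.2f} log units "
          f"to the solubility error")

print()
print("logS = 0.5 - 0.01 (MP - 25) - logP: every degree of melting point")
print("costs 0.01 log units of predicted solubility, so the accuracy of a")
print("melting-point model bounds the accuracy of GSE solubilities.")
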