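"""Predict kLa for an operating condition and the oxygen-limited density.

Composes medium properties -> dimensionless groups -> Sherwood correlation
-> kLa, then bounds the supportable cell density by equating the oxygen
transfer rate to the culture's uptake rate.
"""

from vwbr import correlation as co, io, physchem as pc

table = io.load_table1_areas().set_index("volume_mL")
c = io.load_table3_constants()["experimental"]

# 60 rpm at 21 C, the span of working volumes
props = pc.medium_properties(21.0)
for volume in (100.0, 60.0):
    op = pc.OperatingPoint(
        N=pc.rpm_to_rev_s(60.0), V=volume * 1e-6,
        A=float(table.loc[volume, "area_cm2"]) * 1e-4, T=21.0,
    )
    kla, kl = co.predict_kla(op, props, c)
    print(f"{volume:5.0f} mL @ 60 rpm: kLa = {kla * 3600:.2f} 1/h, "
          f"kL = {kl:.2e} m/s")

# Stem-cell culture condition: 37 C, 60 mL, 30 rpm; qO2 literature bounds
props37 = pc.medium_properties(37.0)
op = pc.OperatingPoint(
    N=pc.rpm_to_rev_s(30.0), V=60e-6,
    A=float(table.loc[60.0, "specific_area_per_m"]) * 60e-6, T=37.0,
)
kla, _ = co.predict_kla(op, props37, c)
for qo2 in (1.10e-16, 1.00e-18):
    X = co.max_cell_density(kla, props37.C_sat, qo2)
    print(f"qO2 = {qo2:.2e} mol/cell/s -> X = {X / 1e6:.3g} cells/mL")
# The two densities bound the oxygen-limited operating window; their ratio
# is exactly the ratio of the uptake-rate bounds (110x).
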