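"""From molecular composition to H_II wedge geometry.

Builds the lipid wedge unit cell of a DOPE inverted hexagonal phase from
the four molecular parameters (intrinsic curvature C0, headgroup width
d_H, backbone width d_BB, lipid volume V_lipid) plus the lattice
parameter a, and prints the derived structural quantities.
"""

from hexsaxs import build_wedge, derived_structure, load_lipid

lipid = load_lipid("DOPE")
a = 76.9  # lattice parameter from Bragg peaks, A

wedge = build_wedge(
    C0=-0.0409,      # 1/A, neutral-plane curvature (negative: bends to water)
    d_H=4.0,         # A, headgroup shell width
    d_BB=7.0,        # A, glycerol-backbone shell width
    V_lipid=1142.0,  # A^3, lipid molecular volume
    a=a,
    lipid=lipid,
)
derived = derived_structure(wedge, a)

print(f"neutral-plane radius    R_0  = {wedge.R_0:6.2f} A")
print(f"water-core radius       R_W  = {derived['R_W']:6.2f} A")
print(f"hydrocarbon width       d_HC = {derived['d_HC']:6.2f} A")
print(f"head-to-head distance   d_HH = {derived['d_HH']:6.2f} A")
print(f"area per lipid at R_0   A_0  = {derived['A_0']:6.2f} A^2")
print(f"shape parameter         s    = {derived['s']:6.3f}")
for shell in ("H", "BB", "HC"):
    print(
        f"shell {shell:>2}: {wedge.n_W[shell]:5.2f} waters/lipid, "
        f"contrast {wedge.sld[shell]:+.4f} e/A^3"
    )

# A_0 ~ 62 A^2 and s ~ 1.3 > 1 mark DOPE as a strongly inverted-cone
# (H_II-forming) lipid; the negative hydrocarbon contrast is the X-ray
# signature of the chain region being less electron-dense than water.
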