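"""Cross-correlation maps and coupled bond disruption.

Two couplings are demonstrated: a planted anti-correlated Cα pair (the
loop near the DNA-reading lysine moving against the dimerization
interface) recovered from the normalized cross-correlation map, and the
joint disruption of the Lys120 and Arg280 hydrogen bonds measured as a
co-disruption fraction.
"""

import quartersite as qs
from quartersite.interface_contacts import _lys_contact, saltbridge_contacts

template = qs.build_template("AGGCATGTGC")
window = qs.FrameWindow.tail(1.0)

# --- planted anti-correlated pair -----------------------------------------
truth = qs.PlantedTruth(
    contacts=[], n_frames=2000, bend_deg=0.0,
    corr_pair=("A:120:CA", "A:180:CA"), corr_sign=-1,
)
ensemble, _ = qs.generate(template, truth, seed=6)
sel = qs.SelectionSpec(chain_id="A", atom_name="CA")
cmap = qs.covariance_map(ensemble, sel, window=window)
i = cmap.labels.index(("A", 120))
j = cmap.labels.index(("A", 180))
print(f"C(res120, res180) = {cmap.matrix[i, j]:+.2f}  (planted anti-correlation)")

block = qs.submap(cmap, (100, 140), (175, 185))
print(f"loop x interface sub-map shape: {block.matrix.shape}, "
      f"min entry {block.matrix.min():+.2f}")

# --- coupled Lys120/Arg280 disruption --------------------------------------
ens2, _ = qs.coupled_disruption_scenario(template, p_joint=0.4, n_frames=2000, seed=8)
lys_contact, _, _ = _lys_contact(ens2, template.mapping, "Q1", 2, False, 3.5)
s_lys = qs.distance_series(ens2, lys_contact, window)
s_arg = qs.distance_series(
    ens2, saltbridge_contacts(ens2, template.mapping, "Q1")["A"], window
)
r, co = qs.cooccupancy_correlation(s_lys, s_arg)
print(f"\ncoupled scenario: Pearson r = {r:+.2f}, "
      f"co-disruption fraction = {co:.2f} (planted joint rate 0.40)")
print("when the lysine bond breaks, the arginine bond breaks with it — the "
      "coupling the distance-series correlation is designed to expose")
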