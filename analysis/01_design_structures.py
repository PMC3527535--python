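"""Design the two model systems and verify every printed constraint.

Reproduces (or re-verifies, when the bundled fixtures are present) the two
native targets: protein K, a 41-bead lattice chain whose backbone ties a
trefoil knot with its minimal knotted segment on beads 3-22, and protein
U, its unknotted 40-bead control built by re-routing a few backbone
segments.  Writes the conformations, their contact maps and a constraint
report under results/design/.
"""

import json
from pathlib import Path

import pandas as pd

from knotfold import designer
from knotfold.designer import superposition_overlap, verify_native
from knotfold.knots import find_knot_core
from knotfold.lattice import abs_contact_order, write_conformation

OUT = Path("results/design")
OUT.mkdir(parents=True, exist_ok=True)

K = designer.load_native("K")
U = designer.load_native("U")

rows = []
for name, s in (("K", K), ("U", U)):
    write_conformation(OUT / f"protein_{name}.txt", s.conformation)
    pd.DataFrame(sorted(s.native_map), columns=["i", "j"]).to_csv(
        OUT / f"contacts_{name}.tsv", sep="\t", index=False
    )
    violations = verify_native(s)
    core = find_knot_core(s.conformation)
    rows.append(
        {
            "protein": name,
            "n_beads": s.n,
            "n_contacts": len(s.native_map),
            "abs_contact_order": abs_contact_order(s.native_map),
            "knot": s.knot.type_label,
            "alexander_det": s.knot.alexander_det,
            "knot_core": str(core),
            "violations": "; ".join(violations) or "none",
        }
    )

overlap = superposition_overlap(K, U)
summary = pd.DataFrame(rows)
summary.to_csv(OUT / "design_summary.tsv", sep="\t", index=False)
(OUT / "overlap.json").write_text(json.dumps({"overlap_percent": overlap}))

print(summary.to_string(index=False))
print(f"\nbead-site overlap K/U under optimal superposition: {overlap:.1f}%")
print("every printed design constraint verified" if
      all(r["violations"] == "none" for r in rows) else "CONSTRAINT VIOLATIONS FOUND")
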