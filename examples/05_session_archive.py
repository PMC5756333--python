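"""Persist a whole session and reproduce it exactly.

Saves a data map (matrices, recipes, attached reports) into a single zip
archive, reloads it, saves again, and shows the two archives are
byte-identical under a frozen clock — the property that makes shared
sessions exactly reproducible.  Also prints the assembled markdown report
of the active node.
"""

import tempfile
from pathlib import Path

from exprmap import assemble_report, create_map, load_state, save_state
from exprmap.simulate import SimulationSpec, simulate_counts

matrix, design, _ = simulate_counts(SimulationSpec(n_features=120, n_samples=8, seed=9))
dmap = create_map(matrix, "raw", clock=lambda: "2024-01-01T00:00:00+00:00")
n1 = dmap.normalize_node(dmap.root_id, "median_ratio", min_detect_frac=0.3)
dmap.set_active(n1)
dmap.add_recipe("sample_qc_stats")

with tempfile.TemporaryDirectory() as tmp:
    a, b = Path(tmp) / "a.zip", Path(tmp) / "b.zip"
    save_state(dmap, a)
    loaded = load_state(a)
    save_state(loaded, b)
    print(f"archive size: {a.stat().st_size} bytes")
    print(f"save -> load -> save byte-identical: {a.read_bytes() == b.read_bytes()}")
    print(f"nodes restored: {len(loaded.nodes)}, recipes restored: {len(loaded.recipes)}")
    print()
    print("\n".join(assemble_report(loaded, n1).splitlines()[:12]))
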