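"""Simulate a bundle, fingerprint it, and inspect the written reports.

`run_simulate` writes ensemble.pdb + mapping.toml + truth.json;
`run_fingerprint` consumes the bundle and writes every report table plus a
manifest whose checksums make the run reproducible byte for byte.
"""

import json
import tempfile
from pathlib import Path

import quartersite as qs

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    paths = qs.run_simulate(tmp / "bundle", n_frames=300, seed=11)
    print("bundle:", ", ".join(p.name for p in paths.values()))

    cfg = qs.RunConfig.from_bundle(tmp / "bundle", tmp / "report")
    results = qs.run_fingerprint(cfg)

    manifest = results["manifest"]
    print(f"frames analysed: {manifest['n_frames']}")
    print("reports written:", ", ".join(sorted(manifest["outputs"])))

    print("\nsalt bridges (A-D, % of window frames):")
    for quarter, bridges in sorted(results["saltbridges"].items()):
        print(f"  {quarter}: " + "  ".join(f"{v:5.1f}" for v in bridges.as_tuple()))

    bend = {row["segment"]: row["bend_deg"] for row in results["bend"]}
    print(f"\nbend over the full duplex: {bend['full']:.1f} deg "
          "(the default truth plants 18.8)")
    print("re-running with the same seed reproduces every file checksum in "
          "the manifest")
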