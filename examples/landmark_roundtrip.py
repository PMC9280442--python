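"""Emit synthetic MeshLab picked-points files and re-measure them.

Writes one .pp landmark file per synthetic specimen (two landmarks per element
side, under a random rigid transform), then runs the landmark-to-length
pipeline on the directory and verifies that every length is recovered at the
2-decimal measurement precision.
"""

import tempfile
from pathlib import Path

from limbasym import SyntheticParams, generate_landmark_files, generate_measurements, run_pipeline
from limbasym.morphometry import round2

params = SyntheticParams(n_specimens=10, mu_pa=-2.0, sigma_pa=1.0, digit_noise=0.0, seed=7)
truth = generate_measurements(params)

with tempfile.TemporaryDirectory() as tmp:
    for specimen_id, doc in generate_landmark_files(truth, params).items():
        (Path(tmp) / f"{specimen_id}.pp").write_text(doc)
    result = run_pipeline(tmp)

recovered = {r.specimen_id: (r.left_length, r.right_length) for r in result.asymmetry.itertuples()}
exact = sum(
    recovered[m.specimen_id] == (round2(m.left_length), round2(m.right_length)) for m in truth
)
print(result.asymmetry[["specimen_id", "left_length", "right_length",
                        "percent_asymmetry", "direction"]].to_string(index=False))
print(f"\n{exact}/{len(truth)} specimens recovered exactly at 2 dp")

# With zero digitization noise the distance between the two landmarks of each
# side equals the generated length, so the re-measured table matches the truth
# exactly at the 0.01 mm measurement resolution.
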