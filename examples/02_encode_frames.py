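"""Preprocess one subject and encode the grayscale Hb frames.

Runs the filter / window / baseline / 2-SD masking stage, renders the
5x10-pixel frames for the three modalities (oxy, deoxy, mixed OD), and
reports how many candidate frames survive the missing-value exclusion.
Writes one squash-resized 256x256 PNG of each modality.
"""

from pathlib import Path

from nirsclench import (ChannelLayout, CohortConfig, build_image_set,
                        generate_recording, preprocess_recording)
from nirsclench.imaging import export_png

rec = generate_recording(CohortConfig(seed=1), 0)
epoch = preprocess_recording(rec)  # 0.2 Hz low-pass, 2-SD mask
print(f"masked samples: {epoch.n_masked()} "
      f"of {2 * (600 + 550) * 22} (rest+clench, both species)")

layout = ChannelLayout.default()
images = build_image_set(epoch, layout)
for m in ("oxy", "deoxy", "od"):
    labels = [im.label for im in images[m]]
    print(f"{m:>5}: {labels.count('rest')} rest + {labels.count('clench')} "
          f"clench valid frames (of 600 + 550 candidates)")
# OD frames need every channel valid in BOTH species, so the OD count is
# never larger than either single-species count.

out = Path("scratch") / "frames"
out.mkdir(parents=True, exist_ok=True)
for m in ("oxy", "deoxy", "od"):
    export_png(images[m][0], out / f"frame_{m}.png", side=256)
print(f"wrote example PNGs to {out}/")
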