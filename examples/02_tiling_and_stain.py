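"""Tile one synthetic slide and Macenko-normalise a kept tile.

Shows the two preprocessing stages: Otsu-thresholded sliding-window tiling
(256 x 256 tiles, stride 128, tiles with more than 75% background
discarded) and stain normalisation of a tile into the reference
haematoxylin/eosin basis.
"""

import numpy as np

from duomil import (
    ArrayRegionReader,
    SynthConfig,
    estimate_stain_profile,
    generate_dataset,
    normalize_patch,
    tile_slide,
)

slide = generate_dataset(SynthConfig(n_normal=1, n_positive=0, n_cases=1,
                                     slide_size=1024, seed=3))[0]
reader = ArrayRegionReader(slide.image)
grid = tile_slide(reader, slide_id=slide.slide_id)

print(f"{slide.slide_id}: {len(grid.tiles)} grid tiles, "
      f"{len(grid.kept_tiles)} kept after background rejection")

tile = grid.kept_tiles[0]
patch = reader.read_region(tile.x, tile.y, tile.size, tile.size)
profile = estimate_stain_profile(patch)
print("estimated stain matrix (columns: haematoxylin, eosin):")
print(np.round(profile.stain_matrix, 3))
print("robust max concentrations:", np.round(profile.max_concentrations, 3))

normalised = normalize_patch(patch)
shift = np.abs(normalised.astype(int) - patch.astype(int)).mean()
print(f"mean per-pixel change after normalisation: {shift:.2f} grey levels")
print("(small for slides already close to the reference stain basis; "
      "larger for slides from a colour-shifted scanner)")
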