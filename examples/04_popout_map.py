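"""Pop-out: a singleton in a texture array attracts the map's maximum.

Trains the toy static model on Gabor-texture scenes (about a minute), then
scores intensity and orientation singleton arrays.  The global argmax of
each saliency map should land on the odd element even though the model has
never seen these test arrays -- only the ensemble statistics.
"""

import numpy as np

from ctxsal import compute_map, gen_popout_image, make_demo_static_model

print("training the static toy model on texture scenes ...")
model, _ = make_demo_static_model(seed=0)

for kind in ("intensity", "orientation"):
    img, pos = gen_popout_image(kind, seed=4)
    m = compute_map(img, model)
    am = np.unravel_index(np.argmax(m.scores), m.shape)
    loc = (m.offset[0] + am[0], m.offset[1] + am[1])
    dist = np.hypot(loc[0] - pos[0], loc[1] - pos[1])
    print(
        f"{kind:12s} singleton at {pos}, map argmax at {loc} "
        f"({dist:.1f} px off; <= 3 px is inside the center-mask footprint)"
    )
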