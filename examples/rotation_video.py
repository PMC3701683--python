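"""Export a rotation video of a single-panel scene.

The default plan is one full clockwise turn at one degree per frame:
360 frames at 30 FPS, i.e. a 12 s video with 735 x 534 frames. Here we
render a quick 8-frame GIF (45 degrees per frame) at a small size.
"""

import bnv
from bnv.fixtures import make_two_hemisphere_surface

frames, duration = bnv.video_plan()
print(f"default plan : {frames} frames at 30 FPS = {duration:.0f} s, 735x534 px")

surface = make_two_hemisphere_surface(seed=1)
config = bnv.DisplayConfig(layout="single", detail="low", width_px=160, height_px=120)
scene = bnv.build_scene(surface=surface, config=config)
bnv.render_video(scene, "rotation.gif", fps=10, degrees_per_frame=45, size=(160, 120))

quick_frames, quick_duration = bnv.video_plan(fps=10, degrees_per_frame=45)
print(f"this demo    : {quick_frames} frames = {quick_duration:.1f} s at 160x120 px")
print("wrote rotation.gif (the scene spins clockwise through a full circle)")
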