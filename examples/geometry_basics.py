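"""Where does a gaze ray land on the partner's face?

Builds a facial plane from three landmarks, intersects a binocular gaze
ray pair with it, and classifies the hit against the 6.3 cm eye-area rule.
"""
import numpy as np

from dyadgaze import (GazeRay, LandmarkSet, angular_error,
                      binocular_intersection, classify_gaze,
                      estimate_facial_plane, project_to_plane_coords)

# the partner's face, 65 cm away (cm; y up, z toward the observer)
partner = LandmarkSet(left_eye=[-3.1, 60, 65], right_eye=[3.1, 60, 65],
                      mouth=[0, 53, 65], nose=[0, 56.5, 65])
plane = estimate_facial_plane(partner, toward=[0, 60, 0])

# both eyes fixate a point 2 cm to the side of the partner's left eye
target = np.array([-5.1, 60.0, 65.0])
left = GazeRay([-3.1, 60, 0], target - np.array([-3.1, 60, 0]))
right = GazeRay([3.1, 60, 0], target - np.array([3.1, 60, 0]))

hit = binocular_intersection(left, right, plane)
label = classify_gaze(hit, partner)
u, v = project_to_plane_coords(hit, plane)

print(f"binocular intersection: {np.round(hit.point, 3)} (t = {hit.ray_parameter:.1f} cm)")
print(f"in-plane coordinates:   u = {u:+.2f} cm, v = {v:+.2f} cm")
print(f"AOI label:              {label.name}")
print(f"angular error to the left-eye landmark: "
      f"{angular_error(left, partner.left_eye):.2f} deg")
# The hit lands 2 cm from the left-eye landmark -- inside the 6.3 cm eye
# disc, so the frame counts as gaze to the eye area (label EYE).
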