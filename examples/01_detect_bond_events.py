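"""Harvest transition-state candidates from a scripted trajectory.

A two-molecule hydrogen system is scripted so that one H-H bond breaks
while a new one forms a few frames later. The bond-event detector scans
the frame-by-frame adjacency matrices, debounces vibrational chatter,
groups nearby flips into one reactive event and returns the mid-event
frame as the transition-state candidate geometry.
"""

from mechkit.bbfs import detect_events, extract_candidates, group_events
from mechkit.synthfix import EventScript, ScriptedEvent, make_trajectory

script = EventScript(
    elements=["H", "H", "H", "H"],
    base_coords=[[0, 0, 0], [0.74, 0, 0], [10, 0, 0], [11.5, 0, 0]],
    events=[
        ScriptedEvent(pair=(0, 1), kind="broken", start_frame=40,
                      end_frame=60, start_dist=0.74, end_dist=3.0),
        ScriptedEvent(pair=(2, 3), kind="formed", start_frame=42,
                      end_frame=62, start_dist=1.5, end_dist=0.70),
    ],
    n_frames=100,
    vibration_amplitude=0.002,
    seed=7,
)
trajectory, ground_truth = make_trajectory(script)

events = detect_events(trajectory)
print("detected bond events:")
for ev in events:
    print(f"  frame {ev.frame:3d}  pair {ev.pair}  {ev.kind}")
print("ground truth matches detection:", events == ground_truth)

candidates = extract_candidates(trajectory, group_events(events))
for cand in candidates:
    print(f"candidate window {cand.window}, active atoms {sorted(cand.active_atoms)}")
    print("  reactant adjacency:\n", cand.reactant_graph.A.astype(int))
    print("  product adjacency:\n", cand.product_graph.A.astype(int))
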