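"""Build a constraint-satisfying arena configuration for one participant.

Every room carries an overlearned goal location (OPA) and a new goal
location (NPA).  Placement rules: 3 a.u. wall margin, a 3-second walking
distance from the starting corners, NPA at least 7 a.u. from its room's
OPA and 2 a.u. from every other room's OPA.
"""

from eventarena import build_participant

config = build_participant(n_rooms=36, seed=1)
geo = config.geometry

room = config.rooms[0]
print(f"{config.n_rooms} rooms, arena {geo.width:g} x {geo.depth:g} a.u.")
print(f"room 0: OPA ({room.opa.x:.1f}, {room.opa.y:.1f}), "
      f"NPA ({room.npa.x:.1f}, {room.npa.y:.1f})")
print(f"  NPA-to-own-OPA distance: {room.npa.distance_to(room.opa):.2f} a.u. "
      "(constraint: >= 7)")
closest_other = min(room.npa.distance_to(r.opa)
                    for r in config.rooms if r.room_id != 0)
print(f"  NPA-to-other-OPA minimum: {closest_other:.2f} a.u. "
      "(constraint: >= 2)")
# The JSON snapshot can be stored and reloaded to reproduce the session.
print(f"config JSON is {len(config.to_json())} bytes")
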