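# Sanctioned posts vs providers in position at the two study facilities.
# Stored as metadata only; no index computation uses these numbers.
DH:
  consultant_obgyn: {post: 1, in_position: 1}
  consultant_anesthesia: {post: 1, in_position: 0}
  anesthetist_medical_officer: {post: 1, in_position: 1}
  consultant_pediatrics: {post: 1, in_position: 2}
  resident_medical_officer: {post: 2, in_position: 2}
  pathologist: {post: 1, in_position: 1}
  emergency_medical_officer: {post: 3, in_position: 1}
  medical_officer_outpatients: {post: 14, in_position: 7}
  senior_staff_nurse: {post: 38, in_position: 31}
  staff_nurse_project: {post: 0, in_position: 10}
  medical_technologist_laboratory: {post: 1, in_position: 2}
  peon_ward_boy: {post: 17, in_position: 18}
  guard: {post: 4, in_position: 1}
  aya_maid: {post: 10, in_position: 7}
  sweeper: {post: 19, in_position: 13}
MCWC:
  medical_officer_trained: {post: 1, in_position: 1}
  anesthetist_medical_officer: {post: 1, in_position: 1}
  staff_nurse_project: {post: 0, in_position: 1}
  family_welfare_visitor: {post: 1, in_position: 6}
  assistant_nursing_attendant: {post: 2, in_position: 3}
  peon_ward_boy: {post: 1, in_position: 2}
  guard: {post: 0, in_position: 2}
  aya_maid: {post: 0, in_position: 1}
  sweeper: {post: 1, in_position: 3}
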