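# Conversion rules from source pose layouts to the 17-keypoint gait body model.
# Every target keypoint is produced by exactly one rule (direct or midpoint);
# every source joint appears in exactly one category (direct, midpoint source,
# or discarded).  Midpoints are unweighted means of their source set.

gsi17:
  keypoints:
    - head
    - neck
    - shoulder_center
    - spine_center
    - hip_center
    - l_shoulder
    - r_shoulder
    - l_elbow
    - r_elbow
    - l_wrist
    - r_wrist
    - l_hip
    - r_hip
    - l_knee
    - r_knee
    - l_ankle
    - r_ankle
  # 16 bones forming a kinematic tree: axial chain plus bilateral limbs,
  # no left-to-right limb link except through the axial chain.
  edges:
    - [head, neck]
    - [neck, shoulder_center]
    - [shoulder_center, spine_center]
    - [spine_center, hip_center]
    - [shoulder_center, l_shoulder]
    - [shoulder_center, r_shoulder]
    - [l_shoulder, l_elbow]
    - [l_elbow, l_wrist]
    - [r_shoulder, r_elbow]
    - [r_elbow, r_wrist]
    - [hip_center, l_hip]
    - [hip_center, r_hip]
    - [l_hip, l_knee]
    - [l_knee, l_ankle]
    - [r_hip, r_knee]
    - [r_knee, r_ankle]

kinect25:
  # Kinect v2 JointType order (indices 0-24).
  joints:
    - SpineBase        # 0
    - SpineMid         # 1
    - Neck             # 2
    - Head             # 3
    - ShoulderLeft     # 4
    - ElbowLeft        # 5
    - WristLeft        # 6
    - HandLeft         # 7
    - ShoulderRight    # 8
    - ElbowRight       # 9
    - WristRight       # 10
    - HandRight        # 11
    - HipLeft          # 12
    - KneeLeft         # 13
    - AnkleLeft        # 14
    - FootLeft         # 15
    - HipRight         # 16
    - KneeRight        # 17
    - AnkleRight       # 18
    - FootRight        # 19
    - SpineShoulder    # 20
    - HandTipLeft      # 21
    - ThumbLeft        # 22
    - HandTipRight     # 23
    - ThumbRight       # 24
  direct:
    head: Head
    neck: Neck
    shoulder_center: SpineShoulder
    spine_center: SpineMid
    hip_center: SpineBase
    l_shoulder: ShoulderLeft
    r_shoulder: ShoulderRight
    l_elbow: ElbowLeft
    r_elbow: ElbowRight
    l_wrist: WristLeft
    r_wrist: WristRight
    l_hip: HipLeft
    r_hip: HipRight
    l_knee: KneeLeft
    r_knee: KneeRight
    l_ankle: AnkleLeft
    r_ankle: AnkleRight
  midpoints: {}
  discarded:
    - HandLeft
    - HandRight
    - FootLeft
    - FootRight
    - HandTipLeft
    - ThumbLeft
    - HandTipRight
    - ThumbRight
  # Kinect camera frame has z pointing away from the camera; the package
  # convention is z toward the camera.
  negate_z: true

mediapipe33:
  # MediaPipe Pose landmark order (indices 0-32).
  joints:
    - nose               # 0
    - left_eye_inner     # 1
    - left_eye           # 2
    - left_eye_outer     # 3
    - right_eye_inner    # 4
    - right_eye          # 5
    - right_eye_outer    # 6
    - left_ear           # 7
    - right_ear          # 8
    - mouth_left         # 9
    - mouth_right        # 10
    - left_shoulder      # 11
    - right_shoulder     # 12
    - left_elbow         # 13
    - right_elbow        # 14
    - left_wrist         # 15
    - right_wrist        # 16
    - left_pinky         # 17
    - right_pinky        # 18
    - left_index         # 19
    - right_index        # 20
    - left_thumb         # 21
    - right_thumb        # 22
    - left_hip           # 23
    - right_hip          # 24
    - left_knee          # 25
    - right_knee         # 26
    - left_ankle         # 27
    - right_ankle        # 28
    - left_heel          # 29
    - right_heel         # 30
    - left_foot_index    # 31
    - right_foot_index   # 32
  direct:
    head: nose
    l_shoulder: left_shoulder
    r_shoulder: right_shoulder
    l_elbow: left_elbow
    r_elbow: right_elbow
    l_wrist: left_wrist
    r_wrist: right_wrist
    l_hip: left_hip
    r_hip: right_hip
    l_knee: left_knee
    r_knee: right_knee
    l_ankle: left_ankle
    r_ankle: right_ankle
  # Central-axis keypoints absent from MediaPipe are unweighted midpoints.
  # Targets may reference previously computed GSI keypoints (evaluated in
  # listed order), so spine_center and neck build on shoulder/hip centers.
  midpoints:
    shoulder_center: [left_shoulder, right_shoulder]
    hip_center: [left_hip, right_hip]
    spine_center: [gsi:shoulder_center, gsi:hip_center]
    neck: [gsi:head, gsi:shoulder_center]
  discarded:
    - left_eye_inner
    - left_eye
    - left_eye_outer
    - right_eye_inner
    - right_eye
    - right_eye_outer
    - left_ear
    - right_ear
    - mouth_left
    - mouth_right
    - left_pinky
    - right_pinky
    - left_index
    - right_index
    - left_thumb
    - right_thumb
    - left_heel
    - right_heel
    - left_foot_index
    - right_foot_index
  negate_z: false
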