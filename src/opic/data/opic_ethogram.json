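{
  "version_label": "OPIC final",
  "categories": [
    "Time domains",
    "Physical environment",
    "Child global state",
    "Location",
    "Activity",
    "Physical interaction"
  ],
  "codes": [
    {
      "name": "Settling routine",
      "category": "Time domains",
      "type": "STATE",
      "subjects": "either",
      "modifiers": []
    },
    {
      "name": "Lights out",
      "category": "Time domains",
      "type": "POINT",
      "subjects": "either",
      "modifiers": []
    },
    {
      "name": "Sleep onset",
      "category": "Time domains",
      "type": "POINT",
      "subjects": "either",
      "modifiers": []
    },
    {
      "name": "Morning waking",
      "category": "Time domains",
      "type": "POINT",
      "subjects": "either",
      "modifiers": []
    },
    {
      "name": "Noise intrusion",
      "category": "Physical environment",
      "type": "STATE",
      "subjects": "either",
      "modifiers": []
    },
    {
      "name": "Music",
      "category": "Physical environment",
      "type": "STATE",
      "subjects": "either",
      "modifiers": []
    },
    {
      "name": "Bright lighting",
      "category": "Physical environment",
      "type": "STATE",
      "subjects": "either",
      "modifiers": []
    },
    {
      "name": "Sleep",
      "category": "Child global state",
      "type": "STATE",
      "subjects": "child",
      "modifiers": []
    },
    {
      "name": "Night waking",
      "category": "Child global state",
      "type": "STATE",
      "subjects": "child",
      "modifiers": []
    },
    {
      "name": "Movement arousal",
      "category": "Child global state",
      "type": "STATE",
      "subjects": "child",
      "modifiers": []
    },
    {
      "name": "In bed",
      "category": "Location",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Position",
          "values": [
            "lying",
            "sitting",
            "standing",
            "on all fours",
            "crouching",
            "mobile"
          ]
        }
      ]
    },
    {
      "name": "Out of bed",
      "category": "Location",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Position",
          "values": [
            "lying",
            "sitting",
            "standing",
            "on all fours",
            "crouching",
            "mobile"
          ]
        }
      ]
    },
    {
      "name": "Laughing",
      "category": "Activity",
      "type": "POINT",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Reading",
      "category": "Activity",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Singing",
      "category": "Activity",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Playing",
      "category": "Activity",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Eating",
      "category": "Activity",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Drinking",
      "category": "Activity",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Verbalization",
      "category": "Activity",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Rocking",
      "category": "Activity",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Tidying/housekeeping",
      "category": "Activity",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Personal care",
      "category": "Activity",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Electronics",
      "category": "Activity",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Self-stimulating",
      "category": "Activity",
      "type": "STATE",
      "subjects": "either",
      "modifiers": [
        {
          "name": "Helpful to sleep?",
          "values": [
            "soothing",
            "non-soothing",
            "neutral"
          ]
        }
      ]
    },
    {
      "name": "Brief close physical contact",
      "category": "Physical interaction",
      "type": "POINT",
      "subjects": "either",
      "modifiers": []
    },
    {
      "name": "Extended close physical contact",
      "category": "Physical interaction",
      "type": "STATE",
      "subjects": "either",
      "modifiers": []
    }
  ]
}
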