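{
  "pain": [
    "pain", "pains", "painful", "ache", "aches", "achy", "achey", "aching",
    "sore", "soreness", "hurt", "hurts", "hurting", "cramp", "cramps",
    "cramping", "crampy", "tender", "tenderness", "twinge", "twinges",
    "backache", "headache", "headaches"
  ],
  "sleep_and_fatigue": [
    "sleep", "sleeping", "sleepless", "sleepy", "insomnia", "tired",
    "tiredness", "fatigue", "fatigued", "exhausted", "exhaustion", "nap",
    "naps", "napping", "drowsy", "restless", "energy", "wiped out"
  ],
  "hormones_and_emotions": [
    "hormone", "hormones", "hormonal", "estrogen", "progesterone", "hrt",
    "mood", "moods", "moody", "mood swings", "crying", "weepy", "weepies",
    "tearful", "depressed", "depression", "anxiety", "anxious", "emotional",
    "emotions", "irritable", "hot flash", "hot flashes", "hot flush",
    "hot flushes", "menopause", "menopausal"
  ],
  "digestion": [
    "gastritis", "nausea", "nauseous", "nauseated", "vomit", "vomiting",
    "vomitting", "constipation", "constipated", "diarrhea", "diarrhoea",
    "bowel", "bowels", "gas", "gassy", "indigestion", "heartburn",
    "appetite", "stomachache", "tummy trouble", "reflux"
  ],
  "swelling": [
    "swelling", "swollen", "swell", "swelly", "swellybelly", "swelly belly",
    "bloat", "bloated", "bloating", "puffy", "puffiness", "distended",
    "distention", "inflammation", "inflamed"
  ],
  "bleeding": [
    "bleeding", "bleed", "bleeds", "bled", "blood", "bloody", "spotting",
    "spotted", "spotty", "discharge", "clot", "clots", "clotting",
    "hemorrhage", "haemorrhage", "oozing", "staining"
  ],
  "urination": [
    "urinate", "urinating", "urination", "urinary", "urine", "bladder",
    "uti", "pee", "peeing", "incontinence", "incontinent", "void",
    "voiding", "leakage", "leaking", "retention"
  ],
  "intimacy": [
    "intimacy", "intimate", "sex", "sexual", "sexually", "intercourse",
    "libido", "orgasm", "arousal", "lovemaking", "love making", "dtd",
    "celibate"
  ],
  "odd_sensations": [
    "itch", "itches", "itching", "itchy", "burn", "burns", "burning",
    "tingle", "tingles", "tingling", "numb", "numbness", "twitch",
    "twitching", "prickling", "zinger", "zingers", "pins and needles",
    "pulling sensation", "pressure"
  ],
  "drugs": [
    "drug", "drugs", "medication", "medications", "meds", "pills",
    "percocet", "vicodin", "ibuprofen", "tylenol", "motrin", "morphine",
    "oxycodone", "codeine", "narcotic", "narcotics", "painkiller",
    "painkillers", "antibiotic", "antibiotics", "laxative", "laxatives",
    "stool softener"
  ],
  "fever_and_infection": [
    "fever", "feverish", "infection", "infections", "infected",
    "temperature", "chills", "pus", "cellulitis", "abscess", "sepsis",
    "low grade fever"
  ],
  "family": [
    "family", "husband", "hubby", "spouse", "partner", "wife", "kids",
    "children", "child", "daughter", "son", "toddler", "baby", "mom",
    "mother", "dad", "father", "sister", "grandkids", "grandchildren"
  ]
}
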