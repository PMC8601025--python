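{
  "version": "1.0",
  "filter_terms": {
    "covid": ["covid", "coronavirus", "corona"],
    "vaccine": ["vaccine", "vax"]
  },
  "categories": {
    "availability": [
      "alabama", "alaska", "arizona", "arkansas", "california", "colorado",
      "connecticut", "delaware", "florida", "georgia", "hawaii", "idaho",
      "illinois", "indiana", "iowa", "kansas", "kentucky", "louisiana",
      "maine", "maryland", "massachusetts", "michigan", "minnesota",
      "mississippi", "missouri", "montana", "nebraska", "nevada",
      "new hampshire", "new jersey", "new mexico", "new york",
      "north carolina", "north dakota", "ohio", "oklahoma", "oregon",
      "pennsylvania", "rhode island", "south carolina", "south dakota",
      "tennessee", "texas", "utah", "vermont", "virginia", "washington",
      "west virginia", "wisconsin", "wyoming",
      "ny", "nyc", "nj", "ca", "fl", "tx", "az", "pa", "ga", "il", "oh",
      "mi", "wa", "mn", "ma", "md", "va", "nc", "sc", "co", "tn", "wi",
      "mo", "ky", "ks", "dc",
      "new york city", "los angeles", "chicago", "houston", "phoenix",
      "philadelphia", "san antonio", "san diego", "dallas", "austin",
      "seattle", "denver", "boston", "atlanta", "miami", "detroit",
      "minneapolis", "las vegas", "portland", "san francisco",
      "near me", "where to get", "where can i get", "when can i get",
      "how to get", "when will i get", "appointment", "sign up",
      "schedule", "scheduling", "walk in", "drive thru", "location",
      "locations", "site", "sites", "clinic", "clinics", "hospital",
      "hospitals", "health department", "county", "eligibility",
      "eligible", "available", "availability", "register", "registration",
      "distribution", "finder", "waitlist", "supply",
      "cvs", "walgreens", "rite aid", "riteaid", "walmart", "kroger",
      "costco", "publix", "safeway", "sams club", "meijer", "heb",
      "wegmans", "albertsons", "winn dixie"
    ],
    "manufacturer": [
      "pfizer", "moderna", "johnson", "j j", "janssen", "astrazeneca",
      "astra zeneca", "novavax", "biontech"
    ],
    "side_effects_safety": [
      "side effects", "side effect", "safety", "safe", "reaction",
      "blood clot", "blood clots", "fever", "allergy", "allergic",
      "pregnant", "pregnancy", "breastfeeding", "problems", "problem",
      "risks", "risk", "dangerous", "danger", "headache", "fatigue",
      "chills", "nausea", "rash", "sore arm", "arm pain",
      "long term effects", "myocarditis", "anaphylaxis", "death", "deaths"
    ],
    "myths_conspiracy": [
      "infertility", "infertile", "sterility", "sterile", "dna",
      "microchip", "5g", "covid from vaccine", "magnet", "magnetic"
    ]
  },
  "pharmacy_names": [
    "cvs", "walgreens", "rite aid", "riteaid", "walmart", "kroger",
    "costco", "publix", "safeway", "sams club", "meijer", "heb",
    "wegmans", "albertsons", "winn dixie"
  ],
  "variants": {
    "vaccines": "vaccine",
    "vaccination": "vaccine",
    "vaccinations": "vaccine",
    "vaccinated": "vaccine",
    "vacine": "vaccine",
    "vacines": "vaccine",
    "vaccin": "vaccine",
    "vacinne": "vaccine",
    "vaxine": "vaccine",
    "phizer": "pfizer",
    "pfiser": "pfizer",
    "pfizers": "pfizer",
    "fizer": "pfizer",
    "moderena": "moderna",
    "maderna": "moderna",
    "modernas": "moderna",
    "jansen": "janssen",
    "jannsen": "janssen",
    "astrazenica": "astrazeneca",
    "astrazenca": "astrazeneca",
    "walgreen": "walgreens",
    "walmarts": "walmart",
    "sam's": "sams",
    "appointments": "appointment",
    "reactions": "reaction",
    "allergies": "allergy",
    "microchips": "microchip"
  },
  "general_patterns": [
    "covid vaccine", "covid 19 vaccine", "coronavirus vaccine",
    "corona vaccine", "covid vaccine update", "covid vaccine updates",
    "covid vaccine news", "covid vaccine info",
    "covid vaccine information", "new covid vaccine", "the covid vaccine",
    "covid vaccine cdc", "cdc covid vaccine"
  ]
}
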