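# Synthetic reconstruction of a Parkinson's-disease term dictionary.
# One term per line, optional TAB-separated tag in
# {symptom, medication, advocacy, exercise, other}.
# Assembled from clinical PD vocabulary (motor and non-motor symptoms),
# common drug names, advocacy/community phrases, exercise programs popular
# in the PD community, and deliberately ambiguous everyday terms, so that
# both relevant and irrelevant posts can contain hits.
parkinson	other
parkinsons	other
parkinsonism	other
parkinson disease	other
tremor	symptom
tremors	symptom
trembling	symptom
shaking	symptom
shaky	symptom
shakes	symptom
rigidity	symptom
stiffness	symptom
stiff	symptom
slowness	symptom
bradykinesia	symptom
dyskinesia	symptom
dystonia	symptom
freezing	symptom
frozen	symptom
shuffling	symptom
shuffle	symptom
stooped	symptom
hunched	symptom
balance	symptom
imbalance	symptom
unsteady	symptom
fall	symptom
falls	symptom
fell	symptom
falling	symptom
fallen	symptom
stumbled	symptom
tripped	symptom
dizzy	symptom
dizziness	symptom
lightheaded	symptom
fainting	symptom
drooling	symptom
swallowing	symptom
choking	symptom
slurred	symptom
soft voice	symptom
hoarse	symptom
mumbling	symptom
handwriting	symptom
micrographia	symptom
cramp	symptom
cramps	symptom
fatigue	symptom
fatigued	symptom
tired	symptom
exhausted	symptom
exhaustion	symptom
insomnia	symptom
sleepless	symptom
sleep	symptom
nightmares	symptom
vivid dreams	symptom
restless legs	symptom
constipation	symptom
bladder	symptom
urinary	symptom
incontinence	symptom
loss of smell	symptom
anosmia	symptom
apathy	symptom
anxiety	symptom
anxious	symptom
depression	symptom
depressed	symptom
hallucinations	symptom
confusion	symptom
memory	symptom
forgetful	symptom
brain fog	symptom
numbness	symptom
tingling	symptom
pain	symptom
aching	symptom
aches	symptom
weakness	symptom
frozen shoulder	symptom
masked face	symptom
blank stare	symptom
rigid	symptom
spasm	symptom
spasms	symptom
twitching	symptom
twitch	symptom
levodopa	medication
carbidopa	medication
sinemet	medication
rytary	medication
entacapone	medication
comtan	medication
stalevo	medication
rasagiline	medication
azilect	medication
selegiline	medication
amantadine	medication
gocovri	medication
pramipexole	medication
mirapex	medication
ropinirole	medication
requip	medication
rotigotine	medication
neupro	medication
apomorphine	medication
benztropine	medication
cogentin	medication
trihexyphenidyl	medication
safinamide	medication
xadago	medication
istradefylline	medication
nourianz	medication
dopamine	medication
dopamine agonist	medication
mao b inhibitor	medication
deep brain stimulation	medication
dbs	medication
duopa	medication
focused ultrasound	medication
neurologist	medication
movement disorder specialist	medication
physical therapy	medication
occupational therapy	medication
speech therapy	medication
medication	medication
meds	medication
dose	medication
dosage	medication
prescription	medication
side effects	medication
wearing off	medication
off time	medication
on time	medication
infusion	medication
parkinson foundation	advocacy
moving day	advocacy
team fox	advocacy
michael j fox	advocacy
davis phinney	advocacy
awareness walk	advocacy
world parkinsons day	advocacy
tulip	advocacy
fundraiser	advocacy
support group	advocacy
research study	advocacy
clinical trial	advocacy
caregiver	advocacy
care partner	advocacy
advocacy	advocacy
donate	advocacy
foundation	advocacy
exercise	exercise
exercising	exercise
workout	exercise
gym	exercise
boxing	exercise
rock steady boxing	exercise
yoga	exercise
tai chi	exercise
cycling	exercise
spin class	exercise
treadmill	exercise
walking group	exercise
pedaling	exercise
dance class	exercise
stretching	exercise
pilates	exercise
zumba	exercise
marathon	exercise
5k	exercise
hike	exercise
hiking	exercise
doctor	other
hospital	other
appointment	other
clinic	other
therapy	other
diagnosis	other
diagnosed	other
symptoms	other
disease	other
chronic	other
slow	other
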